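# Feast/famine shift run: 4 h feast in CGXII + 4% glucose, 12 h carbon
# famine (CGXII - GLC - PCA), 2 h re-established feast.  All times in
# minutes, rates in 1/min unless suffixed otherwise.
preset: famine_carbon
seeds: [1, 2, 3, 4, 5]
n_founders: 4
outdir: famine_run
stages: [simulate, render, quantify, track, analyze, classify]
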