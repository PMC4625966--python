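# Reference cultivation in BHI complex medium at pH 7.0 with 46.3 uM
# calcein-AM; growth-rate windows of 6 frames (48 min).
preset: reference_bhi_ph70
seeds: [1]
n_founders: 1
outdir: bhi_run
stages: [simulate, render, quantify, track, analyze]
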