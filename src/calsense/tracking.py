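"""Frame-to-frame linking, division detection and lineage forests.

Cells in monolayer chambers are sessile: between consecutive frames a
cell's centroid moves only by growth-induced pushing, so a greedy
nearest-centroid assignment with a displacement gate (default 2 um per
frame) suffices.  A division is declared when one cell is replaced by
two nearby regions whose combined area matches the mother's within
+-30 %.  A track that disappears for a single frame and reappears in
place is bridged (segmentation dropout tolerance).  The result is a
forest of lineage nodes exportable as Newick trees (branch length =
track duration in minutes) with per-node attribute tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Obs",
    "FrameLink",
    "LineageNode",
    "LineageForest",
    "link_frames",
    "build_lineage",
    "track_observations",
    "export_lineage",
]


@dataclass(frozen=True)
class Obs:
    """Minimal per-cell observation used by the tracker."""

    frame: int
    label: int
    area: float            # um^2
    x: float               # um
    y: float               # um
    mean_fluor: float
    t_min: float


def obs_from_table(table: pd.DataFrame, pixel_size: float) -> "list[list[Obs]]":
    """Group a measurement table into per-frame observation lists
    (frames without cells yield empty lists)."""
    if len(table) == 0:
        return []
    n = int(table["frame"].max()) + 1
    frames: list[list[Obs]] = [[] for _ in range(n)]
    for row in table.itertuples(index=False):
        frames[int(row.frame)].append(Obs(
            frame=int(row.frame), label=int(row.label),
            area=float(row.area_um2),
            x=float(row.centroid_x) * pixel_size,
            y=float(row.centroid_y) * pixel_size,
            mean_fluor=float(row.mean_fluor_au), t_min=float(row.t_min)))
    return frames


@dataclass
class FrameLink:
    """Assignment between two consecutive frames (indices into the
    respective observation lists)."""

    matches: "list[tuple[int, int]]" = field(default_factory=list)
    divisions: "list[tuple[int, tuple[int, int]]]" = field(default_factory=list)
    appearances: "list[int]" = field(default_factory=list)
    disappearances: "list[int]" = field(default_factory=list)


def mask_overlaps(mask_t: np.ndarray, mask_t1: np.ndarray) -> "dict":
    """Pixel-overlap counts between labels of two consecutive frames:
    ``{(label_t, label_t1): n_pixels}`` over non-background pixels."""
    a = np.asarray(mask_t).ravel()
    b = np.asarray(mask_t1).ravel()
    sel = (a > 0) & (b > 0)
    if not sel.any():
        return {}
    pairs = a[sel].astype(np.int64) * (int(b.max()) + 1) + b[sel]
    uniq, counts = np.unique(pairs, return_counts=True)
    base = int(b.max()) + 1
    return {(int(u // base), int(u % base)): int(c)
            for u, c in zip(uniq, counts)}


def link_frames(obs_t: "list[Obs]", obs_t1: "list[Obs]",
                max_displacement: float = 2.0,
                division_area_tol: float = 0.30,
                overlap: "Optional[dict]" = None,
                pixel_size: float = 0.065) -> FrameLink:
    """Greedy linking of frame t to frame t+1.

    Cells in the chamber are sessile, so a cell's mask overlaps its own
    next-frame mask far more than any neighbour's: when ``overlap``
    (from :func:`mask_overlaps`) is given, candidate pairs are ranked by
    overlap fraction first and centroid distance second; without masks,
    plain nearest-centroid ranking is used.  Identical frames give the
    identity matching.  A mother matched by two new regions whose
    summed area is within ``division_area_tol`` of hers becomes a
    division; unmatched old cells are disappearances and unmatched new
    cells appearances.
    """
    link = FrameLink()
    if not obs_t or not obs_t1:
        link.disappearances = list(range(len(obs_t)))
        link.appearances = list(range(len(obs_t1)))
        return link

    p0 = np.array([[o.x, o.y] for o in obs_t])
    p1 = np.array([[o.x, o.y] for o in obs_t1])
    d = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=2)

    match_of_old: dict[int, int] = {}
    match_of_new: dict[int, int] = {}

    if overlap:
        # each new region claims the old region it overlaps most; an old
        # region claimed by two new regions whose areas sum to its own
        # is a division
        ov_px = np.zeros_like(d)
        idx_old = {o.label: i for i, o in enumerate(obs_t)}
        idx_new = {o.label: j for j, o in enumerate(obs_t1)}
        for (la, lb), px in overlap.items():
            i, j = idx_old.get(la), idx_new.get(lb)
            if i is not None and j is not None:
                ov_px[i, j] = px
        claims: dict[int, list[int]] = {}
        for j in range(len(obs_t1)):
            if ov_px[:, j].max() > 0:
                claims.setdefault(int(np.argmax(ov_px[:, j])), []).append(j)
        for i, kids in claims.items():
            kids.sort(key=lambda j: -ov_px[i, j])
            if len(kids) == 1:
                match_of_old[i] = kids[0]
                match_of_new[kids[0]] = i
                continue
            j1, j2 = kids[0], kids[1]
            combined = obs_t1[j1].area + obs_t1[j2].area
            if len(kids) == 2 and \
                    abs(combined - obs_t[i].area) <= division_area_tol * obs_t[i].area:
                link.divisions.append((i, (j1, j2)))
                match_of_new[j1] = i
                match_of_new[j2] = i
            else:
                # keep the strongest claim, release the others
                match_of_old[i] = j1
                match_of_new[j1] = i
        # distance fallback for claim-less new regions (e.g. newly
        # visible cells after a dropout)
        for j in range(len(obs_t1)):
            if j in match_of_new:
                continue
            free = [i for i in range(len(obs_t))
                    if i not in match_of_old
                    and i not in {ii for ii, _ in link.divisions}
                    and d[i, j] <= max_displacement]
            if free:
                i = min(free, key=lambda i: d[i, j])
                match_of_old[i] = j
                match_of_new[j] = i
    else:
        cand = np.argwhere(d <= max_displacement)
        order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
        for idx in order:
            i, j = int(cand[idx, 0]), int(cand[idx, 1])
            if i in match_of_old or j in match_of_new:
                continue
            match_of_old[i] = j
            match_of_new[j] = i
        # division: a free new region close to a matched mother whose
        # two candidate daughters sum to her area
        for j in range(len(obs_t1)):
            if j in match_of_new:
                continue
            near = sorted((i for i in match_of_old
                           if d[i, j] <= max_displacement),
                          key=lambda i: d[i, j])
            for i in near:
                j0 = match_of_old[i]
                combined = obs_t1[j0].area + obs_t1[j].area
                if abs(combined - obs_t[i].area) \
                        <= division_area_tol * obs_t[i].area:
                    link.divisions.append((i, (j0, j)))
                    del match_of_old[i]
                    match_of_new[j0] = i
                    match_of_new[j] = i
                    break

    link.matches = sorted(match_of_old.items())
    taken_new = set(match_of_new)
    link.appearances = [j for j in range(len(obs_t1)) if j not in taken_new]
    taken_old = set(match_of_old) | {i for i, _ in link.divisions}
    link.disappearances = [i for i in range(len(obs_t)) if i not in taken_old]
    return link


@dataclass
class LineageNode:
    track_id: int
    parent_track: Optional[int]
    observations: "list[Obs]"
    children: "list[int]" = field(default_factory=list)
    end_reason: str = "ongoing"       # ongoing | divided | lysed | lost
    generation: int = 0

    @property
    def start_frame(self) -> int:
        return self.observations[0].frame

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def duration_min(self) -> float:
        return self.observations[-1].t_min - self.observations[0].t_min

    def validate(self):
        frames = [o.frame for o in self.observations]
        if any(b - a < 1 or b - a > 2 for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.track_id}: frame gaps > 1")
        if len(self.children) > 2:
            raise ValueError(f"track {self.track_id}: more than 2 children")


@dataclass
class LineageForest:
    roots: "list[int]"
    index: "dict[int, LineageNode]"

    def validate(self):
        seen = set()
        for tid, node in self.index.items():
            node.validate()
            if node.parent_track is not None:
                parent = self.index.get(node.parent_track)
                if parent is None:
                    raise ValueError(f"track {tid}: missing parent")
                if parent.end_frame >= node.start_frame:
                    raise ValueError(f"track {tid}: starts before parent ends")
            for o in node.observations:
                key = (o.frame, o.label)
                if key in seen:
                    raise ValueError(f"observation {key} in two tracks")
                seen.add(key)

    @property
    def n_observations(self) -> int:
        return sum(len(n.observations) for n in self.index.values())

    def edges(self) -> "list[tuple[int, int]]":
        return [(n.parent_track, tid) for tid, n in self.index.items()
                if n.parent_track is not None]


def build_lineage(links: "list[FrameLink]",
                  frames: "list[list[Obs]]",
                  bridge_displacement: float = 2.0) -> LineageForest:
    """Assemble a lineage forest from consecutive frame links.

    ``links[k]`` connects ``frames[k]`` to ``frames[k+1]``.  A track
    that ended at frame k-1 may be bridged to an appearance at frame
    k+1 at the same position (one-frame segmentation dropout).
    """
    if len(links) != max(len(frames) - 1, 0):
        raise ValueError("need one link per consecutive frame pair")
    forest = LineageForest(roots=[], index={})
    next_id = 1
    # track id currently holding each observation index of frame k
    current: dict[int, int] = {}
    recently_lost: dict[int, tuple] = {}   # track_id -> (frame, x, y)

    def new_track(obs: Obs, parent: Optional[int]) -> int:
        nonlocal next_id
        tid = next_id
        next_id += 1
        gen = 0 if parent is None else forest.index[parent].generation + 1
        forest.index[tid] = LineageNode(
            track_id=tid, parent_track=parent, observations=[obs],
            generation=gen)
        if parent is None:
            forest.roots.append(tid)
        else:
            forest.index[parent].children.append(tid)
        return tid

    for i, obs in enumerate(frames[0] if frames else []):
        current[i] = new_track(obs, None)

    for k, link in enumerate(links):
        nxt: dict[int, int] = {}
        for i, j in link.matches:
            tid = current[i]
            forest.index[tid].observations.append(frames[k + 1][j])
            nxt[j] = tid
        for i, (j1, j2) in link.divisions:
            tid = current[i]
            # a transient segmentation merge looks like a division one
            # frame after a neighbouring track was lost: if a recently
            # lost track sits on one daughter, bridge it instead
            bridged_division = False
            for j_lost, j_keep in ((j1, j2), (j2, j1)):
                o = frames[k + 1][j_lost]
                for lost_tid, (fr, x, y) in list(recently_lost.items()):
                    if fr == k - 1 and np.hypot(o.x - x, o.y - y) \
                            <= bridge_displacement:
                        node = forest.index[lost_tid]
                        node.observations.append(o)
                        node.end_reason = "ongoing"
                        del recently_lost[lost_tid]
                        nxt[j_lost] = lost_tid
                        forest.index[tid].observations.append(
                            frames[k + 1][j_keep])
                        nxt[j_keep] = tid
                        bridged_division = True
                        break
                if bridged_division:
                    break
            if bridged_division:
                continue
            forest.index[tid].end_reason = "divided"
            nxt[j1] = new_track(frames[k + 1][j1], tid)
            nxt[j2] = new_track(frames[k + 1][j2], tid)
        for j in link.appearances:
            o = frames[k + 1][j]
            bridged = None
            for tid, (fr, x, y) in list(recently_lost.items()):
                if fr == k - 1 and np.hypot(o.x - x, o.y - y) <= bridge_displacement:
                    bridged = tid
                    break
            if bridged is not None:
                node = forest.index[bridged]
                node.observations.append(o)
                node.end_reason = "ongoing"
                del recently_lost[bridged]
                nxt[j] = bridged
            else:
                nxt[j] = new_track(o, None)
        for i in link.disappearances:
            tid = current[i]
            node = forest.index[tid]
            node.end_reason = "lost"
            last = node.observations[-1]
            recently_lost[tid] = (k, last.x, last.y)
        recently_lost = {t: v for t, v in recently_lost.items()
                         if v[0] >= k - 1}
        current = nxt

    forest.validate()
    return forest


def track_observations(cell_table: pd.DataFrame, pixel_size: float,
                       max_displacement: float = 2.0,
                       n_frames: Optional[int] = None,
                       masks: Optional[np.ndarray] = None) -> LineageForest:
    """Convenience: link all frames of a measurement table and build the
    forest.  ``masks`` (per-frame label images matching the table's
    labels) enable overlap-based linking, which is markedly more robust
    in crowded colonies."""
    frames = obs_from_table(cell_table, pixel_size)
    if n_frames is not None and len(frames) < n_frames:
        frames = frames + [[] for _ in range(n_frames - len(frames))]
    links = []
    for k in range(len(frames) - 1):
        ov = (mask_overlaps(masks[k], masks[k + 1])
              if masks is not None else None)
        links.append(link_frames(frames[k], frames[k + 1], max_displacement,
                                 overlap=ov, pixel_size=pixel_size))
    return build_lineage(links, frames, bridge_displacement=max_displacement)


def _newick(node: LineageNode, forest: LineageForest) -> str:
    name = f"c{node.track_id}"
    length = f"{node.duration_min:g}"
    if not node.children:
        return f"{name}:{length}"
    kids = ",".join(_newick(forest.index[c], forest) for c in node.children)
    return f"({kids}){name}:{length}"


def export_lineage(forest: LineageForest, fmt: str = "newick",
                   path=None):
    """Export a forest as Newick (one tree per root, branch lengths in
    minutes) plus a node-attribute table, or as an edge-list table."""
    if fmt == "newick":
        trees = "\n".join(f"({_newick(forest.index[r], forest)});"
                          for r in forest.roots)
        attrs = pd.DataFrame(
            [(t.track_id, t.parent_track, t.start_frame, t.end_frame,
              t.end_reason, t.generation, len(t.observations),
              t.duration_min,
              float(np.mean([o.area for o in t.observations])),
              float(np.mean([o.mean_fluor for o in t.observations])))
             for t in forest.index.values()],
            columns=["track_id", "parent_track", "birth_frame", "end_frame",
                     "end_reason", "generation", "n_obs", "duration_min",
                     "mean_area_um2", "mean_fluor_au"])
        if path is not None:
            from pathlib import Path

            p = Path(path)
            p.with_suffix(".nwk").write_text(trees + "\n")
            attrs.to_csv(p.with_suffix(".attrs.csv"), index=False)
        return trees, attrs
    if fmt == "tabular":
        edges = pd.DataFrame(
            [(t.track_id, t.parent_track, t.start_frame, t.end_frame,
              t.end_reason) for t in forest.index.values()],
            columns=["track_id", "parent_track", "birth_frame", "end_frame",
                     "end_reason"])
        if path is not None:
            edges.to_csv(path, index=False)
        return edges
    raise ValueError(f"unknown export format {fmt!r}")
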