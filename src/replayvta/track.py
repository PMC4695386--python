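"""Track geometry: linearization, along-track distances, and candidate paths.

The track is a small graph of straight segments. Position is expressed as a
single linear coordinate obtained by adjoining the segments end-to-end;
because adjacency in that coordinate is partly artificial (arms that meet at
a junction may sit far apart in the 1-D layout), all distances between
linear coordinates go through an along-track distance function built on the
segment graph, never through naive subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path


@dataclass
class Segment:
    name: str
    node_start: str
    node_end: str
    length: float
    xy_start: np.ndarray
    xy_end: np.ndarray
    offset: float = 0.0  # linear coordinate of node_start


@dataclass
class Path:
    """A directed traversal of the track, with its own 0..length coordinate."""

    path_id: str
    steps: list  # list of (segment index, direction +1/-1)
    length: float = 0.0


class LinearTrack:
    """Segment-graph track with a dense along-track distance function."""

    def __init__(
        self,
        segments: list[Segment],
        paths: list[Path],
        bin_width: float = 10.0,
        reward_regions: list[tuple[float, float]] | None = None,
        reward_sites_cm: list[float] | None = None,
    ) -> None:
        self.segments = segments
        self.paths = paths
        self.bin_width = float(bin_width)
        self.reward_regions = [tuple(r) for r in (reward_regions or [])]
        self.reward_sites_cm = list(reward_sites_cm or [])

        offset = 0.0
        nodes: list[str] = []
        for seg in self.segments:
            seg.offset = offset
            offset += seg.length
            for n in (seg.node_start, seg.node_end):
                if n not in nodes:
                    nodes.append(n)
        self.length = offset
        self.nodes = nodes

        n = len(nodes)
        adj = np.full((n, n), np.inf)
        np.fill_diagonal(adj, 0.0)
        for seg in self.segments:
            i, j = nodes.index(seg.node_start), nodes.index(seg.node_end)
            adj[i, j] = min(adj[i, j], seg.length)
            adj[j, i] = adj[i, j]
        self._node_dist = shortest_path(adj, method="FW", directed=False)

        self.n_bins = int(np.ceil(self.length / self.bin_width))
        self.bin_centers = (np.arange(self.n_bins) + 0.5) * self.bin_width
        for p in self.paths:
            p.length = float(sum(self.segments[i].length for i, _ in p.steps))

    # ---------------------------------------------------------------- geometry

    def _segment_index(self, lin: np.ndarray) -> np.ndarray:
        edges = np.array([s.offset for s in self.segments] + [self.length])
        idx = np.clip(np.searchsorted(edges, lin, side="right") - 1, 0,
                      len(self.segments) - 1)
        return idx

    def distance(self, a, b) -> np.ndarray:
        """Along-track distance between linear coordinates (broadcasting)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = np.broadcast_arrays(a, b)
        sa, sb = self._segment_index(a), self._segment_index(b)
        offs = np.array([s.offset for s in self.segments])
        lens = np.array([s.length for s in self.segments])
        ns = np.array([self.nodes.index(s.node_start) for s in self.segments])
        ne = np.array([self.nodes.index(s.node_end) for s in self.segments])

        da_start = a - offs[sa]
        da_end = offs[sa] + lens[sa] - a
        db_start = b - offs[sb]
        db_end = offs[sb] + lens[sb] - b

        nd = self._node_dist
        best = np.minimum.reduce([
            da_start + nd[ns[sa], ns[sb]] + db_start,
            da_start + nd[ns[sa], ne[sb]] + db_end,
            da_end + nd[ne[sa], ns[sb]] + db_start,
            da_end + nd[ne[sa], ne[sb]] + db_end,
        ])
        same = sa == sb
        best = np.where(same, np.minimum(best, np.abs(a - b)), best)
        return best

    def linearize(self, xy: np.ndarray, tolerance_cm: float = 10.0):
        """Project 2-D tracked positions onto the track.

        Returns (linear coordinate, off-track flags). Samples farther than
        `tolerance_cm` from every segment are flagged and linearly
        interpolated from their neighbors.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        n = xy.shape[0]
        best_d = np.full(n, np.inf)
        best_lin = np.zeros(n)
        for seg in self.segments:
            p0, p1 = seg.xy_start, seg.xy_end
            v = p1 - p0
            vv = float(v @ v)
            t = np.clip(((xy - p0) @ v) / vv, 0.0, 1.0) if vv > 0 else np.zeros(n)
            proj = p0 + t[:, None] * v
            d = np.linalg.norm(xy - proj, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_lin[better] = seg.offset + t[better] * seg.length
        flagged = best_d > tolerance_cm
        if flagged.any() and not flagged.all():
            ok = ~flagged
            best_lin[flagged] = np.interp(
                np.where(flagged)[0], np.where(ok)[0], best_lin[ok]
            )
        return best_lin, flagged

    def to_xy(self, lin: np.ndarray) -> np.ndarray:
        """Inverse of linearize for points exactly on the track."""
        lin = np.atleast_1d(np.asarray(lin, dtype=float))
        idx = self._segment_index(lin)
        out = np.zeros((lin.size, 2))
        for i, seg in enumerate(self.segments):
            sel = idx == i
            if not sel.any():
                continue
            t = (lin[sel] - seg.offset) / seg.length
            out[sel] = seg.xy_start + t[:, None] * (seg.xy_end - seg.xy_start)
        return out

    # ------------------------------------------------------------------- paths

    def path_to_linear(self, path: Path, s) -> np.ndarray:
        """Map a path coordinate (0..path.length) to the track's linear coord."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, path.length - 1e-9)
        out = np.zeros_like(s)
        cum = 0.0
        for seg_i, direction in path.steps:
            seg = self.segments[seg_i]
            sel = (s >= cum) & (s < cum + seg.length)
            local = s[sel] - cum
            if direction > 0:
                out[sel] = seg.offset + local
            else:
                out[sel] = seg.offset + seg.length - local
            cum += seg.length
        return out

    def reward_bin_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        for lo, hi in self.reward_regions:
            mask |= (self.bin_centers >= lo) & (self.bin_centers < hi)
        return mask

    def in_reward_region(self, lin) -> np.ndarray:
        lin = np.asarray(lin, dtype=float)
        out = np.zeros(lin.shape, dtype=bool)
        for lo, hi in self.reward_regions:
            out |= (lin >= lo) & (lin < hi)
        return out

    # ------------------------------------------------------------ constructors

    @classmethod
    def linear(cls, length: float = 200.0, reward_margin: float = 10.0,
               bin_width: float = 10.0) -> "LinearTrack":
        """Straight track with a reward well at each end."""
        seg = Segment("track", "A", "B", length,
                      np.array([0.0, 0.0]), np.array([length, 0.0]))
        paths = [
            Path("outbound", [(0, +1)]),
            Path("inbound", [(0, -1)]),
        ]
        regions = [(0.0, reward_margin), (length - reward_margin, length)]
        return cls([seg], paths, bin_width, regions, [0.0, length])

    @classmethod
    def swm(cls, arm: float = 75.0, central: float = 150.0,
            reward_margin: float = 10.0, bin_width: float = 10.0) -> "LinearTrack":
        """End-to-end T maze: two force arms, a central arm, two choice arms.

        Segments are adjoined in the run direction of the choice phase:
        force reward sites -> force point (fp) -> choice point (cp) ->
        choice reward sites. Four candidate paths connect each force reward
        site to each choice reward site.
        """
        a = float(arm)
        c = float(central)
        fp, cp = np.array([0.0, 0.0]), np.array([c, 0.0])
        r3, r4 = np.array([0.0, a]), np.array([0.0, -a])
        r1, r2 = np.array([c, a]), np.array([c, -a])
        segments = [
            Segment("forceL", "R3", "fp", a, r3, fp),
            Segment("forceR", "R4", "fp", a, r4, fp),
            Segment("central", "fp", "cp", c, fp, cp),
            Segment("choiceL", "cp", "R1", a, cp, r1),
            Segment("choiceR", "cp", "R2", a, cp, r2),
        ]
        paths = [
            Path("R3-R1", [(0, +1), (2, +1), (3, +1)]),
            Path("R3-R2", [(0, +1), (2, +1), (4, +1)]),
            Path("R4-R1", [(1, +1), (2, +1), (3, +1)]),
            Path("R4-R2", [(1, +1), (2, +1), (4, +1)]),
        ]
        track = cls(segments, paths, bin_width, None, None)
        # linear coordinates of the four reward wells (R3, R4, R1, R2)
        wells = [0.0, track.segments[1].offset,
                 track.segments[3].offset + a, track.segments[4].offset + a]
        track.reward_regions = [
            (0.0, reward_margin),
            (track.segments[1].offset, track.segments[1].offset + reward_margin),
            (track.segments[3].offset + a - reward_margin, track.segments[3].offset + a),
            (track.segments[4].offset + a - reward_margin, track.segments[4].offset + a),
        ]
        track.reward_sites_cm = wells
        return track
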