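"""Skeleton extraction and epsilon-neighborhood pattern linking.

At each analysis time the *skeleton* is the set of strict interior local
maxima of the energy surface ``E(f, t)`` along the frequency axis (zero
first and negative second derivative on the discrete grid).  Skeleton
points at consecutive analysis times whose frequencies differ by at most
``epsilon`` are chained into *oscillatory patterns*: each pattern tracks
one oscillatory component of the signal through time.

Linking is greedy nearest-first: candidate (pattern head, new point) pairs
are processed by ascending frequency distance, ties broken toward the
lower frequency, each head extended at most once and each point used at
most once.  Unmatched points start new patterns; a frame with no match
(or an empty frame) terminates a pattern for good — patterns never merge,
split, or bridge gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cwt_engine import TimeFrequencySurface


@dataclass
class LinkingParams:
    """Tunable parameters of skeleton extraction and linking.

    ``epsilon`` is the frequency tolerance in Hz for chaining skeleton
    points across consecutive frames (default 0.04 Hz = 10 sampling
    periods at 250 Hz read on the frequency axis).  ``max_skeletons``
    caps the number of maxima kept per frame (largest energies win).
    """

    epsilon: float = 0.04
    max_skeletons: int = 25

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_skeletons < 1:
            raise ValueError("max_skeletons must be >= 1")


@dataclass
class SkeletonFrame:
    """Local maxima of ``E(., t)`` at one analysis time.

    Points are sorted by descending energy and capped at
    ``max_skeletons``.  ``edge`` marks points inside the cone of
    influence (wavelet support crossing a record edge).
    """

    t: float
    freqs: np.ndarray
    energies: np.ndarray
    edge: np.ndarray

    def __len__(self) -> int:
        return self.freqs.size


@dataclass
class OscillatoryPattern:
    """A chain of skeleton points tracking one oscillatory component."""

    id: int
    times: np.ndarray
    freqs: np.ndarray
    energies: np.ndarray
    edge: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edge is None:
            self.edge = np.zeros(self.times.size, dtype=bool)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def cum_energy(self) -> float:
        return float(self.energies.sum())

    def cum_energy_in_band(self, f_lo: float, f_hi: float) -> float:
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi) & ~self.edge
        return float(self.energies[sel].sum())


def extract_skeleton(
    surface: TimeFrequencySurface, params: LinkingParams | None = None
) -> list[SkeletonFrame]:
    """Per-time strict local maxima of the energy surface.

    Grid endpoints are never reported.  On an exact-tie plateau the
    leftmost cell counts as the maximum.  If a column holds more than
    ``max_skeletons`` maxima, the largest-energy ones are kept.
    """
    params = params or LinkingParams()
    if surface.E is None:
        raise ValueError("surface has no energy; call energy_surface first")
    E = surface.E
    if E.shape[1] < 3:
        raise ValueError("need at least 3 grid frequencies for local maxima")
    d = np.diff(E, axis=1)
    s = np.sign(d)
    # Backward-fill zero slopes with the next nonzero sign so that the
    # leftmost cell of an exact-tie plateau is reported.
    for j in range(s.shape[1] - 2, -1, -1):
        zero = s[:, j] == 0
        if zero.any():
            s[zero, j] = s[zero, j + 1]
    is_max = (s[:, :-1] > 0) & (s[:, 1:] < 0)  # interior cells 1..n-2
    frames: list[SkeletonFrame] = []
    edge_mask = surface.edge_mask
    for k in range(E.shape[0]):
        idx = np.nonzero(is_max[k])[0] + 1
        if idx.size:
            order = np.argsort(E[k, idx])[::-1]
            idx = idx[order][: params.max_skeletons]
        frames.append(
            SkeletonFrame(
                t=float(surface.times[k]),
                freqs=surface.freqs[idx].copy(),
                energies=E[k, idx].copy(),
                edge=(
                    edge_mask[k, idx].copy()
                    if edge_mask is not None
                    else np.zeros(idx.size, dtype=bool)
                ),
            )
        )
    return frames


def link_patterns(
    frames: list[SkeletonFrame], params: LinkingParams | None = None
) -> list[OscillatoryPattern]:
    """Chain skeleton points across consecutive frames into patterns.

    Every skeleton point ends up in exactly one pattern (the partition
    property), consecutive frequencies within a pattern differ by at most
    ``epsilon``, and the procedure is deterministic.
    """
    params = params or LinkingParams()
    finished: list[dict] = []
    active: list[dict] = []
    next_id = 0
    for frame in frames:
        m = len(frame)
        if not active:
            matched_points: set[int] = set()
            survivors: list[dict] = []
        else:
            heads = np.array([p["freqs"][-1] for p in active])
            if m:
                dist = np.abs(heads[:, None] - frame.freqs[None, :])
                # small absolute slack: grid arithmetic makes differences
                # like 0.04 come out a few ulp above epsilon
                cand = np.nonzero(dist <= params.epsilon + 1e-12)
                order = np.lexsort(
                    (heads[cand[0]], frame.freqs[cand[1]], dist[cand])
                )
                used_heads: set[int] = set()
                matched_points = set()
                assign: dict[int, int] = {}
                for a, pt in zip(cand[0][order], cand[1][order]):
                    if a in used_heads or pt in matched_points:
                        continue
                    used_heads.add(a)
                    matched_points.add(pt)
                    assign[a] = pt
            else:
                assign, matched_points = {}, set()
            survivors = []
            for a, pat in enumerate(active):
                if a in assign:
                    pt = assign[a]
                    pat["times"].append(frame.t)
                    pat["freqs"].append(float(frame.freqs[pt]))
                    pat["energies"].append(float(frame.energies[pt]))
                    pat["edge"].append(bool(frame.edge[pt]))
                    survivors.append(pat)
                else:
                    finished.append(pat)
        for pt in range(m):
            if pt in matched_points:
                continue
            survivors.append(
                {
                    "id": next_id,
                    "times": [frame.t],
                    "freqs": [float(frame.freqs[pt])],
                    "energies": [float(frame.energies[pt])],
                    "edge": [bool(frame.edge[pt])],
                }
            )
            next_id += 1
        active = survivors
    finished.extend(active)
    patterns = [
        OscillatoryPattern(
            id=p["id"],
            times=np.asarray(p["times"]),
            freqs=np.asarray(p["freqs"]),
            energies=np.asarray(p["energies"]),
            edge=np.asarray(p["edge"], dtype=bool),
        )
        for p in finished
    ]
    patterns.sort(key=lambda p: p.id)
    return patterns


def dominant_ridge(
    patterns: list[OscillatoryPattern],
    f_lo: float,
    f_hi: float,
    times: np.ndarray,
    min_energy_fraction: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time ridge frequency ``sc(t)`` within a band, with gap flags.

    At each analysis time the reported frequency comes from the admissible
    pattern with the greatest cumulative in-band energy among those that
    have an in-band, non-edge point at that time (ties go to the
    earlier-born pattern).  A pattern is admissible if its cumulative
    in-band energy reaches ``min_energy_fraction`` of the strongest
    pattern's: short-lived noise-born chains carry orders of magnitude
    less energy than fragments of a genuine cardiac component and must
    not supply the ridge by default in moments where the dominant chain
    is broken.  A pattern must also have its median frequency inside the
    band: a chain whose bulk lives outside the band tracks a different
    component, and a brief dip across the band edge must not hijack the
    ridge.  Times covered by no admissible point are NaN and flagged as
    gaps.

    Returns ``(freq_of_t, gap_mask)``.
    """
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    times = np.asarray(times, dtype=float)
    ridge = np.full(times.size, np.nan)
    score = np.full(times.size, -np.inf)
    if times.size > 1:
        dt = times[1] - times[0]
    else:
        dt = 1.0
    cums = []
    for pat in patterns:
        med = float(np.median(pat.freqs))
        cums.append(
            pat.cum_energy_in_band(f_lo, f_hi) if f_lo <= med <= f_hi else 0.0
        )
    cmax = max(cums, default=0.0)
    floor = min_energy_fraction * cmax
    for pat, cum in zip(patterns, cums):
        if cum <= 0 or cum < floor:
            continue
        sel = (pat.freqs >= f_lo) & (pat.freqs <= f_hi) & ~pat.edge
        if not sel.any():
            continue
        idx = np.round((pat.times[sel] - times[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < times.size)
        idx, fsel = idx[ok], pat.freqs[sel][ok]
        better = cum > score[idx]
        score[idx[better]] = cum
        ridge[idx[better]] = fsel[better]
    gap = ~np.isfinite(ridge)
    return ridge, gap


def patterns_to_frame(patterns: list[OscillatoryPattern]):
    """Long-format export (pattern_id, t, sc_hz, energy) as a DataFrame."""
    import pandas as pd

    rows = {
        "pattern_id": np.concatenate([np.full(len(p), p.id) for p in patterns])
        if patterns
        else np.array([], dtype=int),
        "t": np.concatenate([p.times for p in patterns]) if patterns else [],
        "sc_hz": np.concatenate([p.freqs for p in patterns]) if patterns else [],
        "energy": np.concatenate([p.energies for p in patterns]) if patterns else [],
    }
    return pd.DataFrame(rows)
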