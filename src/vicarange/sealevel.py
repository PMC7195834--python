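"""Sea-level curves, elevation-grid habitat classification and concordance.

Three habitat classes follow the lowland-fish convention: below the
high-stand cut (default 60 m a.s.l., flooded during Neogene high stands),
the habitable belt up to the altitudinal limit of the group (default
1,000 m), and uplands above it.  High-stand intervals are extracted from a
eustatic sea-level curve by exact linear-segment algebra, and a
length-preserving permutation test quantifies how much of a set of dated
intervals (node ages, extinction windows) overlaps the high stands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SeaLevelCurve",
    "DEMGrid",
    "HighStandIntervals",
    "classify_dem",
    "habitat_connectivity",
    "extract_highstands",
    "interval_concordance",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class SeaLevelCurve:
    """(age Ma, level m relative to present); ages strictly increasing."""

    ages: np.ndarray
    levels: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.levels.shape:
            raise ValueError("ages and levels must be matching 1-D arrays")
        if len(self.ages) < 2:
            raise ValueError("need at least two curve points")
        if not (np.diff(self.ages) > 0).all():
            raise ValueError("ages must be strictly increasing")
        if not np.isfinite(self.levels).all():
            raise ValueError("levels must be finite")

    @classmethod
    def from_csv(cls, path: str) -> "SeaLevelCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=_header_rows(path))
        return cls(data[:, 0], data[:, 1])


def _header_rows(path: str) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(x) for x in first.strip().split(",")]
        return 0
    except ValueError:
        return 1


@dataclass
class DEMGrid:
    """Rectangular elevation grid (m a.s.l.) with a no-data marker."""

    elevations: np.ndarray
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self):
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValueError("elevation grid must be 2-D")

    def valid_mask(self) -> np.ndarray:
        return self.elevations != self.nodata


@dataclass
class HighStandIntervals:
    """Disjoint [older, younger] Ma intervals, ordered oldest first."""

    intervals: list[tuple[float, float]]

    def __post_init__(self):
        for older, younger in self.intervals:
            if older < younger:
                raise ValueError("intervals must be [older, younger]")
        starts = [o for o, _ in self.intervals]
        if starts != sorted(starts, reverse=True):
            raise ValueError("intervals must be ordered oldest first")

    def total_length(self) -> float:
        return sum(o - y for o, y in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def read_ascii_grid(path: str) -> DEMGrid:
    """Read an ESRI-style ASCII grid (ncols/nrows/.../NODATA_value header)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    grid = np.array(rows)
    if "ncols" in header and grid.shape[1] != int(header["ncols"]):
        raise ValueError("grid width does not match ncols header")
    return DEMGrid(
        grid,
        cell_size=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: DEMGrid, path: str) -> None:
    rows, cols = grid.elevations.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write("xllcorner 0\nyllcorner 0\n")
        fh.write(f"cellsize {grid.cell_size}\nNODATA_value {grid.nodata}\n")
        for row in grid.elevations:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def classify_dem(
    grid: DEMGrid, sea_cut: float = 60.0, upland_cut: float = 1000.0
) -> tuple[np.ndarray, dict[int, int]]:
    """Three-class habitat map.

    Class 1: elevation < ``sea_cut`` (flooded at high stands); class 2:
    ``sea_cut <= elevation <= upland_cut`` (habitable belt, boundary at the
    upland cut inclusive); class 3: elevation > ``upland_cut``.  No-data
    cells are class 0 and excluded from the counts.
    """
    if sea_cut >= upland_cut:
        raise ValueError("sea_cut must be below upland_cut")
    valid = grid.valid_mask()
    if not valid.any():
        raise ValueError("grid is all no-data")
    e = grid.elevations
    classes = np.zeros(e.shape, dtype=int)
    classes[valid & (e < sea_cut)] = 1
    classes[valid & (e >= sea_cut) & (e <= upland_cut)] = 2
    classes[valid & (e > upland_cut)] = 3
    counts = {c: int((classes == c).sum()) for c in (1, 2, 3)}
    return classes, counts


def habitat_connectivity(
    grid: DEMGrid,
    sea_level: float,
    upland_cut: float = 1000.0,
    connectivity: int = 4,
) -> tuple[int, list[int]]:
    """Connected habitable components at a given sea level.

    Habitable cells satisfy ``sea_level <= elevation <= upland_cut``;
    components use 4-connectivity by default (8 via ``connectivity=8``).
    Returns the component count and sizes sorted descending.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    habitable = (
        grid.valid_mask()
        & (grid.elevations >= sea_level)
        & (grid.elevations <= upland_cut)
    )
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if connectivity == 4
        else np.ones((3, 3), dtype=int)
    )
    labeled, n = ndimage.label(habitable, structure=structure)
    sizes = sorted(
        (int(s) for s in ndimage.sum_labels(habitable, labeled, range(1, n + 1))),
        reverse=True,
    )
    return n, sizes


def extract_highstands(curve: SeaLevelCurve, threshold: float) -> HighStandIntervals:
    """Age intervals where the linearly interpolated level >= threshold.

    Crossing ages are solved exactly on each linear segment.  A curve that
    sits exactly at the threshold everywhere yields one full-domain
    interval.
    """
    ages, levels = curve.ages, curve.levels
    above = levels >= threshold
    spans: list[tuple[float, float]] = []  # (young, old) in increasing age
    start: float | None = ages[0] if above[0] else None
    for i in range(len(ages) - 1):
        a0, a1 = ages[i], ages[i + 1]
        l0, l1 = levels[i], levels[i + 1]
        if above[i] != above[i + 1]:
            # exact crossing age on the segment
            x = a0 + (threshold - l0) * (a1 - a0) / (l1 - l0)
            if above[i]:
                spans.append((start, x))
                start = None
            else:
                start = x
    if start is not None:
        spans.append((start, ages[-1]))
    # merge touching spans (can arise if a vertex sits exactly on threshold)
    merged: list[tuple[float, float]] = []
    for young, old in spans:
        if merged and young <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], old))
        else:
            merged.append((young, old))
    out = [(old, young) for young, old in reversed(merged)]
    return HighStandIntervals(out)


def _overlap_sum(targets: np.ndarray, stands: list[tuple[float, float]]) -> float:
    total = 0.0
    for older, younger in targets:
        for so, sy in stands:
            total += max(0.0, min(older, so) - max(younger, sy))
    return total


def interval_concordance(
    target_intervals: list[tuple[float, float]],
    highstands: HighStandIntervals,
    n_perm: int = 10_000,
    root_bound: float = 30.0,
    seed: int = 0,
) -> dict:
    """Overlap of dated target intervals with high stands, plus a permutation
    p-value.

    Overlap fraction = summed overlap length / summed target length.  The
    null repositions each target uniformly (length preserved) within
    ``[0, root_bound]``; the one-tailed p-value is the fraction of null
    overlap fractions >= the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    targets = np.asarray(
        [(float(o), float(y)) for o, y in target_intervals], dtype=float
    )
    if targets.size == 0:
        raise ValueError("no target intervals")
    if (targets[:, 0] < targets[:, 1]).any():
        raise ValueError("targets must be [older, younger]")
    if (targets[:, 0] > root_bound).any() or (targets[:, 1] < 0).any():
        raise ValueError("targets must lie within [0, root_bound]")
    total_len = float((targets[:, 0] - targets[:, 1]).sum())
    stands = highstands.intervals
    if total_len == 0.0:
        # degenerate point intervals: score by containment instead of length
        obs = float(
            np.mean([
                any(so >= o >= sy for so, sy in stands) for o, _ in targets
            ])
        )
        return {"overlap_fraction": obs, "p_value": float("nan"),
                "n_perm": 0, "null_mean": float("nan")}
    obs = _overlap_sum(targets, stands) / total_len
    rng = np.random.default_rng(seed)
    lengths = targets[:, 0] - targets[:, 1]
    null = np.empty(n_perm)
    for i in range(n_perm):
        younger = rng.uniform(0.0, root_bound - lengths)
        permuted = np.column_stack([younger + lengths, younger])
        null[i] = _overlap_sum(permuted, stands) / total_len
    p = float((null >= obs - 1e-12).mean())
    return {
        "overlap_fraction": float(obs),
        "p_value": p,
        "n_perm": n_perm,
        "null_mean": float(null.mean()),
    }
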