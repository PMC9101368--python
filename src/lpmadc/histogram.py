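"""Multi-visit ADC histograms.

A tumor is summarised as integer voxel counts on a fixed grid of ADC bins,
concatenated over one or more imaging visits.  All model fitting operates on
these count arrays; the grid is shared between every tumor entering a model.

Bins are half-open ``[low, high)`` with the final bin closed, so a value
exactly on a lower edge lands in that bin and the top edge is not lost.
Values outside the grid are tallied as *overflow*, never silently dropped:
``in-range counts + overflow == number of input values`` always holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "TumorHistogram",
    "build_histogram",
    "assemble_tumor_histogram",
    "read_histogram_csv",
    "write_histogram_csv",
    "read_adc_csv",
]

#: default ADC range, mm^2/s.  Covers free water (~3e-3) with headroom for
#: viable tumor tissue (~0.5-1.5e-3); 100 bins keeps typical 1e3-1e4 voxel
#: tumors at >=10 expected counts per occupied bin so Poisson chi^2 is valid.
DEFAULT_ADC_RANGE = (0.0, 3.0e-3)
DEFAULT_N_BINS = 100


@dataclass(frozen=True)
class BinGrid:
    """ADC bin edges plus an ordered tuple of visit labels.

    Parameters
    ----------
    adc_edges : array-like
        Strictly increasing bin edges in mm^2/s, at least two.
    visits : sequence of str
        Ordered visit labels, e.g. ``("V1", "V2")``.
    """

    adc_edges: np.ndarray
    visits: tuple[str, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.adc_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("adc_edges must be a 1-D sequence of >= 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("adc_edges must be strictly increasing")
        visits = tuple(str(v) for v in self.visits)
        if len(visits) < 1:
            raise ValueError("at least one visit label is required")
        if len(set(visits)) != len(visits):
            raise ValueError("visit labels must be unique")
        object.__setattr__(self, "adc_edges", edges)
        object.__setattr__(self, "visits", visits)

    @classmethod
    def uniform(
        cls,
        n_bins: int = DEFAULT_N_BINS,
        lo: float = DEFAULT_ADC_RANGE[0],
        hi: float = DEFAULT_ADC_RANGE[1],
        visits: Sequence[str] = ("V1", "V2"),
    ) -> "BinGrid":
        """Uniform grid of ``n_bins`` bins over ``[lo, hi]``."""
        return cls(np.linspace(lo, hi, n_bins + 1), tuple(visits))

    @property
    def n_bins(self) -> int:
        return self.adc_edges.size - 1

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_cells(self) -> int:
        """Total (bin, visit) cells: the length of a flattened histogram."""
        return self.n_bins * self.n_visits

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.adc_edges[:-1] + self.adc_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.adc_edges)

    def subset(self, visits: Sequence[str]) -> "BinGrid":
        missing = [v for v in visits if v not in self.visits]
        if missing:
            raise KeyError(f"visits not on grid: {missing}")
        return BinGrid(self.adc_edges, tuple(visits))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return self.visits == other.visits and np.array_equal(
            self.adc_edges, other.adc_edges
        )

    def __hash__(self) -> int:
        return hash((self.visits, self.adc_edges.tobytes()))


@dataclass
class TumorHistogram:
    """Integer voxel counts over a (bin, visit) grid for one tumor.

    ``counts`` has shape ``(n_bins, n_visits)``; ``flat`` gives the
    column-stacked 1-D view used by the model code (visit-major order:
    all bins of visit 1, then all bins of visit 2, ...).
    """

    tumor_id: str
    cohort: str
    counts: np.ndarray
    grid: BinGrid
    overflow: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.grid.n_bins, self.grid.n_visits):
            raise ValueError(
                f"counts shape {counts.shape} does not match grid "
                f"({self.grid.n_bins}, {self.grid.n_visits})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        if self.total <= 0:
            raise ValueError("histogram must contain at least one voxel")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def flat(self) -> np.ndarray:
        """1-D count vector, visit-major (Fortran) order."""
        return self.counts.reshape(-1, order="F")

    def per_visit(self, visit: str) -> np.ndarray:
        return self.counts[:, self.grid.visits.index(visit)]

    def select_visits(self, visits: Sequence[str]) -> "TumorHistogram":
        sub = self.grid.subset(visits)
        idx = [self.grid.visits.index(v) for v in sub.visits]
        return TumorHistogram(
            self.tumor_id, self.cohort, self.counts[:, idx], sub, self.overflow
        )


def build_histogram(
    adc_values: Iterable[float], grid: BinGrid
) -> tuple[np.ndarray, int]:
    """Bin ADC values onto ``grid``, returning ``(counts, overflow)``.

    Uses the half-open ``[low, high)`` convention with the last bin closed.
    Overflow counts values below the first or above the last edge.
    """
    values = np.asarray(list(adc_values), dtype=float)
    if values.size == 0:
        warnings.warn("empty ADC value list: returning zero histogram")
        return np.zeros(grid.n_bins, dtype=np.int64), 0
    counts, _ = np.histogram(values, bins=grid.adc_edges)
    overflow = int(values.size - counts.sum())
    return counts.astype(np.int64), overflow


def assemble_tumor_histogram(
    per_visit: Mapping[str, np.ndarray],
    visit_subset: Sequence[str],
    adc_edges: np.ndarray,
    tumor_id: str,
    cohort: str = "control",
    overflow: int = 0,
) -> TumorHistogram:
    """Stack per-visit count vectors into a multi-visit tumor histogram.

    Visits are concatenated in the requested order; a missing visit raises
    ``KeyError`` naming it.  The total count equals the sum of the selected
    per-visit totals.
    """
    missing = [v for v in visit_subset if v not in per_visit]
    if missing:
        raise KeyError(f"missing visit(s): {missing}")
    grid = BinGrid(adc_edges, tuple(visit_subset))
    counts = np.column_stack([np.asarray(per_visit[v]) for v in grid.visits])
    return TumorHistogram(tumor_id, cohort, counts, grid, overflow)


# ---------------------------------------------------------------------------
# CSV dialects


def write_histogram_csv(histograms: Sequence[TumorHistogram], path) -> None:
    """Write the long-format histogram CSV:
    tumor_id, cohort, visit, bin_low, bin_high, count."""
    rows = []
    for h in histograms:
        lo, hi = h.grid.adc_edges[:-1], h.grid.adc_edges[1:]
        for j, visit in enumerate(h.grid.visits):
            for b in range(h.grid.n_bins):
                rows.append(
                    (h.tumor_id, h.cohort, visit, lo[b], hi[b], h.counts[b, j])
                )
    df = pd.DataFrame(
        rows, columns=["tumor_id", "cohort", "visit", "bin_low", "bin_high", "count"]
    )
    # shortest-roundtrip float text so bin edges survive a write/read cycle
    # bit-exactly (models demand exact grid equality)
    for col in ("bin_low", "bin_high"):
        df[col] = [repr(float(v)) for v in df[col]]
    df.to_csv(path, index=False)


def read_histogram_csv(path) -> list[TumorHistogram]:
    """Read the long-format histogram CSV back into TumorHistogram objects."""
    # round_trip parsing keeps bin edges bit-exact across a write/read cycle
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"tumor_id", "cohort", "visit", "bin_low", "bin_high", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"histogram CSV {path} missing columns {sorted(missing)}")
    out: list[TumorHistogram] = []
    for tid, sub in df.groupby("tumor_id", sort=False):
        visits = list(dict.fromkeys(sub["visit"]))
        first = sub[sub["visit"] == visits[0]].sort_values("bin_low")
        edges = np.append(first["bin_low"].to_numpy(), first["bin_high"].iloc[-1])
        per_visit = {}
        for v in visits:
            block = sub[sub["visit"] == v].sort_values("bin_low")
            if len(block) != len(first):
                raise ValueError(f"tumor {tid}: inconsistent bin count per visit")
            per_visit[v] = block["count"].to_numpy()
        cohort = str(sub["cohort"].iloc[0])
        out.append(
            assemble_tumor_histogram(per_visit, visits, edges, str(tid), cohort)
        )
    return out


def read_adc_csv(path) -> pd.DataFrame:
    """Read the raw per-voxel ADC CSV (tumor_id, visit, adc_value)."""
    df = pd.read_csv(path)
    required = {"tumor_id", "visit", "adc_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ADC CSV {path} missing columns {sorted(missing)}")
    return df
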