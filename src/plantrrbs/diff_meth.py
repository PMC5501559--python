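"""Differential cytosine methylation between two lines.

Replicate call tables of a control line and an epiline are united at
positions reaching the informative-nucleotide floor in *every*
replicate of both lines; per-replicate coverage is median-normalized;
counts are then pooled per line and each position is tested with a
two-sided Fisher exact test on the pooled 2x2 table
[[C_control, T_control], [C_epiline, T_epiline]].  p-values are
adjusted with Benjamini-Hochberg and a position is reported as a
differentially methylated cytosine (DMC) when q < 0.01 and the pooled
level difference exceeds 25 percentage points in absolute value;
"hypo" means the epiline is the lower of the two.

The exact test is computed by exhaustive hypergeometric enumeration
with exact integer weights, so tied table probabilities are handled
without floating-point tie tolerances: p is the sum of probabilities of
all tables with the observed margins whose probability does not exceed
that of the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .meth_call import MethylationCall
from .read_simulator import Key


@dataclass
class DiffConfig:
    """Thresholds and normalization for the two-line comparison."""

    min_informative: int = 10
    q_threshold: float = 0.01
    delta_threshold: float = 25.0
    normalization: str = "median"  # or "none"
    adjust: str = "fdr_bh"

    def __post_init__(self) -> None:
        if self.min_informative < 1 or self.q_threshold <= 0 or self.delta_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.normalization not in ("median", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class UnitedMatrix:
    """Counts for positions covered in every replicate of both lines.

    ``counts`` has shape (n_positions, n_replicates, 2) with the last
    axis holding (Ci, Ti); control replicates come first.
    """

    keys: list[Key]
    contexts: list[str]
    counts: np.ndarray
    n_control: int
    n_epiline: int

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.keys), self.n_control + self.n_epiline, 2):
            raise ValueError("counts shape inconsistent with keys/replicates")

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-line pooled (Ci, Ti): two arrays of shape (n_positions, 2)."""
        ctrl = self.counts[:, : self.n_control, :].sum(axis=1)
        epi = self.counts[:, self.n_control:, :].sum(axis=1)
        return ctrl, epi


@dataclass(frozen=True)
class DmcRecord:
    """One differentially methylated cytosine with its evidence."""

    contig: str
    position: int
    strand: str
    context: str
    control_c: int
    control_t: int
    epiline_c: int
    epiline_t: int
    delta_level: float  # (epiline - control) * 100
    p: float
    q: float
    direction: str  # "hypo" or "hyper"


def unite(
    control: Sequence[Sequence[MethylationCall]],
    epiline: Sequence[Sequence[MethylationCall]],
    config: DiffConfig | None = None,
) -> UnitedMatrix:
    """Inner join of all replicates at the per-replicate coverage floor."""
    config = config or DiffConfig()
    tables: list[dict[Key, tuple[int, int]]] = []
    contexts: dict[Key, str] = {}
    for rep in [*control, *epiline]:
        table = {}
        for call in rep:
            if call.total >= config.min_informative:
                table[call.key] = (call.c_count, call.t_count)
                contexts[call.key] = call.context
        tables.append(table)
    common = sorted(set(tables[0]).intersection(*map(set, tables[1:]))) if tables else []
    counts = np.zeros((len(common), len(tables), 2), dtype=np.int64)
    for i, key in enumerate(common):
        for j, table in enumerate(tables):
            counts[i, j] = table[key]
    return UnitedMatrix(
        keys=list(common),
        contexts=[contexts[k] for k in common],
        counts=counts,
        n_control=len(control),
        n_epiline=len(epiline),
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def normalize_coverage(matrix: UnitedMatrix, method: str = "median") -> UnitedMatrix:
    """Median-based coverage normalization across replicates.

    Each replicate's (Ci, Ti) counts are scaled by the ratio of the
    median of all replicates' median depths to that replicate's own
    median depth, rounding half-up; levels are preserved to within
    rounding and every position keeps at least one informative count.
    """
    if method == "none" or matrix.counts.shape[0] == 0 or matrix.counts.shape[1] < 2:
        return matrix
    if method != "median":
        raise ValueError(f"unknown normalization {method!r}")
    depths = matrix.counts.sum(axis=2).astype(float)  # (n_pos, n_rep)
    medians = np.median(depths, axis=0)
    target = float(np.median(medians))
    scaled = matrix.counts.copy()
    for j, med in enumerate(medians):
        if med == 0:
            continue
        f = target / med
        if f == 1.0:
            continue
        scaled[:, j, :] = _round_half_up(matrix.counts[:, j, :] * f)
        # zero-count protection: a covered position must stay covered
        dead = (scaled[:, j, :].sum(axis=1) == 0) & (matrix.counts[:, j, :].sum(axis=1) > 0)
        if dead.any():
            prefer_c = matrix.counts[dead, j, 0] >= matrix.counts[dead, j, 1]
            scaled[dead, j, 0] = np.where(prefer_c, 1, 0)
            scaled[dead, j, 1] = np.where(prefer_c, 0, 1)
    return UnitedMatrix(matrix.keys, matrix.contexts, scaled, matrix.n_control, matrix.n_epiline)


def exact_test(c1: int, t1: int, c2: int, t2: int) -> float:
    """Two-sided Fisher exact p for [[c1, t1], [c2, t2]].

    Sum of hypergeometric probabilities (margins fixed) of every table
    at most as probable as the observed one.  Integer weights
    C(r1, k) * C(r2, K - k) make the comparison exact.
    """
    for v in (c1, t1, c2, t2):
        if v < 0:
            raise ValueError("negative cell count")
    r1, r2, K = c1 + t1, c2 + t2, c1 + c2
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or K == 0 or K == n:
        return 1.0
    w_obs = comb(r1, c1) * comb(r2, c2)
    num = 0
    for k in range(max(0, K - r2), min(K, r1) + 1):
        w = comb(r1, k) * comb(r2, K - k)
        if w <= w_obs:
            num += w
    return num / comb(n, K)


def call_dmcs(matrix: UnitedMatrix, config: DiffConfig | None = None) -> list[DmcRecord]:
    """Test every united position and report those passing both thresholds."""
    config = config or DiffConfig()
    if not matrix.keys:
        return []
    ctrl, epi = matrix.pooled()
    p_values = np.array(
        [
            exact_test(int(c[0]), int(c[1]), int(e[0]), int(e[1]))
            for c, e in zip(ctrl, epi)
        ]
    )
    q_values = multipletests(p_values, method=config.adjust)[1]
    records: list[DmcRecord] = []
    for i, key in enumerate(matrix.keys):
        cc, ct = int(ctrl[i, 0]), int(ctrl[i, 1])
        ec, et = int(epi[i, 0]), int(epi[i, 1])
        level_c = cc / (cc + ct)
        level_e = ec / (ec + et)
        delta = (level_e - level_c) * 100.0
        if q_values[i] < config.q_threshold and abs(delta) > config.delta_threshold:
            records.append(
                DmcRecord(
                    key[0], key[1], key[2], matrix.contexts[i],
                    cc, ct, ec, et, delta, float(p_values[i]), float(q_values[i]),
                    "hypo" if delta < 0 else "hyper",
                )
            )
    return records


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_DMC_HEADER = (
    "contig\tstart\tend\tstrand\tcontext\tcontrol_c\tcontrol_t\tepiline_c\tepiline_t\t"
    "delta\tp\tq\tdirection\n"
)


def write_dmc_tsv(records: Iterable[DmcRecord], path: str | Path) -> None:
    """BED-compatible DMC table (start/end columns are 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_DMC_HEADER)
        for r in records:
            fh.write(
                f"{r.contig}\t{r.position}\t{r.position + 1}\t{r.strand}\t{r.context}\t"
                f"{r.control_c}\t{r.control_t}\t{r.epiline_c}\t{r.epiline_t}\t"
                f"{r.delta_level:.3f}\t{r.p:.6g}\t{r.q:.6g}\t{r.direction}\n"
            )


def write_unite_tsv(matrix: UnitedMatrix, path: str | Path) -> None:
    n_rep = matrix.n_control + matrix.n_epiline
    cols = [
        f"{line}{j + 1}_{x}"
        for line, n in (("control", matrix.n_control), ("epiline", matrix.n_epiline))
        for j in range(n)
        for x in ("c", "t")
    ]
    assert len(cols) == 2 * n_rep
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tcontext\t" + "\t".join(cols) + "\n")
        for i, key in enumerate(matrix.keys):
            flat = "\t".join(str(int(v)) for v in matrix.counts[i].reshape(-1))
            fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{matrix.contexts[i]}\t{flat}\n")
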