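"""Per-site read counts and their windowed summaries.

The ingestion boundary is a per-individual TSV of read counts at a fixed
set of biallelic sites (``chrom  pos  derived  total``, 1-based
positions).  From these we build

* pairwise window statistics: the expected number of pairwise differences
  ``D_w`` and the number of overlapping sites ``N_w`` per window (input to
  the pair IBD HMM), and
* within-individual window statistics: mismatch sums ``Delta_w`` over
  sites with >= 2 reads and the count ``M_w`` of such sites (input to the
  ROH HMM),

plus the background pairwise difference rate ``p0`` (cohort median of
genome-wide D/N over all pairs).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GenomeLayout

__all__ = [
    "SiteReadCounts",
    "PairWindowData",
    "ROHInput",
    "pair_site_difference",
    "aggregate_pair_windows",
    "within_individual_diffs",
    "estimate_p0",
    "cohort_pair_totals",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_window_table",
]


@dataclass
class SiteReadCounts:
    """Read counts of one individual over the shared site universe.

    ``data`` maps chromosome name to ``(pos, derived, total)`` arrays with
    1-based, sorted, unique positions.
    """

    individual: str
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    validate: bool = True  # generators of known-clean counts may skip checks

    def __post_init__(self) -> None:
        if not self.validate:
            return
        clean: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (pos, der, tot) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            der = np.asarray(der)
            tot = np.asarray(tot)
            if np.any(der > tot):
                raise ValueError(
                    f"{self.individual}/{chrom}: derived count exceeds total"
                )
            if np.any(der < 0) or np.any(tot < 0):
                raise ValueError(f"{self.individual}/{chrom}: negative counts")
            if np.any(np.diff(pos) < 0):
                order = np.argsort(pos, kind="stable")
                pos, der, tot = pos[order], der[order], tot[order]
            if np.any(np.diff(pos) == 0):
                raise ValueError(f"{self.individual}/{chrom}: duplicate positions")
            clean[chrom] = (pos, der, tot)
        self.data = clean

    def mean_depth(self) -> float:
        """Mean reads per target site (coverage proxy)."""
        tot = sum(int(t.sum()) for _, _, t in self.data.values())
        n = sum(len(p) for p, _, _ in self.data.values())
        return tot / n if n else 0.0


@dataclass
class PairWindowData:
    """Windowed expected pairwise differences for one pair of individuals.

    ``0 <= D_w <= N_w`` per window; both may be non-integer (D from
    read-sampling expectations, N after contamination correction).
    """

    pair: tuple[str, str]
    D: np.ndarray
    N: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.D.shape != self.N.shape:
            raise ValueError("D and N must have equal length")
        if np.any(self.D < -1e-9) or np.any(self.D > self.N + 1e-9):
            raise ValueError("require 0 <= D_w <= N_w")

    @property
    def L(self) -> int:
        return len(self.D)

    def totals(self) -> tuple[float, float]:
        return float(self.D.sum()), float(self.N.sum())


@dataclass
class ROHInput:
    """Windowed within-individual mismatch data for the ROH HMM."""

    individual: str
    Delta: np.ndarray
    M: np.ndarray
    mean_depth: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.Delta = np.asarray(self.Delta, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.Delta.shape != self.M.shape:
            raise ValueError("Delta and M must have equal length")
        if np.any(self.Delta < -1e-9) or np.any(self.Delta > self.M + 1e-9):
            raise ValueError("require 0 <= Delta_w <= M_w")

    @property
    def L(self) -> int:
        return len(self.Delta)


def pair_site_difference(nu_i, nu_j):
    """Probability that single reads sampled from i and j differ.

    ``nu`` is the proportion of reads carrying the derived allele; the
    returned value is ``nu_i (1-nu_j) + (1-nu_i) nu_j``, the expectation of
    the pseudo-haploid mismatch over all possible single-read samplings.
    """
    nu_i = np.asarray(nu_i, dtype=float)
    nu_j = np.asarray(nu_j, dtype=float)
    return nu_i * (1.0 - nu_j) + (1.0 - nu_i) * nu_j


def aggregate_pair_windows(
    a: SiteReadCounts, b: SiteReadCounts, grid: GenomeLayout
) -> PairWindowData:
    """Windowed (D, N) for a pair: sites with >= 1 read in both individuals."""
    if set(a.data) != set(b.data):
        raise ValueError(
            f"mismatched chromosome names between {a.individual} and {b.individual}"
        )
    D = np.zeros(grid.L)
    N = np.zeros(grid.L)
    for chrom in grid.chrom_names:
        if chrom not in a.data:
            continue
        pos_a, der_a, tot_a = a.data[chrom]
        pos_b, der_b, tot_b = b.data[chrom]
        if len(pos_a) == len(pos_b) and np.array_equal(pos_a, pos_b):
            ia = ib = slice(None)
            pos = pos_a
        else:  # differing site lists: intersect
            pos, ia, ib = np.intersect1d(pos_a, pos_b, return_indices=True)
        ta, tb = tot_a[ia], tot_b[ib]
        cov = (ta >= 1) & (tb >= 1)
        if not np.any(cov):
            continue
        nu_a = der_a[ia][cov] / ta[cov]
        nu_b = der_b[ib][cov] / tb[cov]
        widx = grid.window_index(chrom, pos[cov] - 1)
        D += np.bincount(widx, weights=pair_site_difference(nu_a, nu_b), minlength=grid.L)
        N += np.bincount(widx, minlength=grid.L)
    return PairWindowData((a.individual, b.individual), D, N)


def within_individual_diffs(
    a: SiteReadCounts, grid: GenomeLayout, estimator: str = "unbiased"
) -> ROHInput:
    """Windowed within-individual mismatch (Delta, M) over sites with >= 2 reads.

    Per site with ``d`` derived out of ``n >= 2`` reads the contribution is
    the probability that two reads drawn from the site differ:

    * ``"unbiased"`` (default): without replacement, ``2 d (n-d) / (n (n-1))``;
      its expectation at a heterozygous site is 1/2 at every depth, matching
      the fixed non-homozygous emission mean ``p2 = p0/2``.
    * ``"plugin"``: with replacement, ``2 nu (1-nu)``.
    """
    if estimator not in ("unbiased", "plugin"):
        raise ValueError(f"unknown estimator {estimator!r}")
    Delta = np.zeros(grid.L)
    M = np.zeros(grid.L)
    for chrom in grid.chrom_names:
        if chrom not in a.data:
            continue
        pos, der, tot = a.data[chrom]
        cov = tot >= 2
        if not np.any(cov):
            continue
        d = der[cov].astype(float)
        n = tot[cov].astype(float)
        if estimator == "unbiased":
            contrib = 2.0 * d * (n - d) / (n * (n - 1.0))
        else:
            nu = d / n
            contrib = 2.0 * nu * (1.0 - nu)
        widx = grid.window_index(chrom, pos[cov] - 1)
        Delta += np.bincount(widx, weights=contrib, minlength=grid.L)
        M += np.bincount(widx, minlength=grid.L)
    return ROHInput(a.individual, Delta, M, mean_depth=a.mean_depth())


def estimate_p0(pairs: list[PairWindowData]) -> float:
    """Background difference rate: median genome-wide D/N ratio over pairs.

    Robust to a minority of related pairs (median property).  The result
    must fall in (0, 0.5); otherwise inference is hopeless and the caller
    should supply ``p0`` explicitly.
    """
    ratios = []
    for p in pairs:
        d, n = p.totals()
        if n > 0:
            ratios.append(d / n)
    if not ratios:
        raise ValueError("no pair has overlapping sites; cannot estimate p0")
    p0 = float(np.median(ratios))
    if not 0.0 < p0 < 0.5:
        raise ValueError(
            f"estimated p0={p0:.4f} outside (0, 0.5); "
            "supply p0 explicitly (e.g. from known unrelated individuals)"
        )
    return p0


def cohort_pair_totals(
    counts: list[SiteReadCounts], max_sites: int | None = None
) -> dict[tuple[str, str], tuple[float, float]]:
    """Genome-wide (sum D, sum N) for every pair, via dense linear algebra.

    Equivalent to summing :func:`aggregate_pair_windows` over windows but
    computed for all pairs at once:  with per-site coverage mask ``m`` and
    masked derived proportion ``a = nu * m``,
    ``sum_s m_i m_j [nu_i + nu_j - 2 nu_i nu_j] = a_i.m_j + m_i.a_j - 2 a_i.a_j``.

    ``max_sites`` evaluates the totals on a deterministic even stride of
    sites (the genome-wide ratio is what callers consume; a few hundred
    thousand sites estimate it to well under 1e-3).
    """
    ids = [c.individual for c in counts]
    chroms = list(counts[0].data)
    S_full = sum(len(counts[0].data[c][0]) for c in chroms)
    stride = max(1, S_full // max_sites) if max_sites else 1
    S = sum(len(counts[0].data[c][0][::stride]) for c in chroms)
    Mmat = np.empty((len(ids), S), dtype=np.float32)
    Amat = np.empty((len(ids), S), dtype=np.float32)
    for k, c in enumerate(counts):
        off = 0
        for chrom in chroms:
            pos, der, tot = c.data[chrom]
            der, tot = der[::stride], tot[::stride]
            n = len(tot)
            m = (tot >= 1).astype(np.float32)
            with np.errstate(divide="ignore", invalid="ignore"):
                nu = np.where(tot > 0, der / np.maximum(tot, 1), 0.0).astype(np.float32)
            Mmat[k, off : off + n] = m
            Amat[k, off : off + n] = nu * m
            off += n
    MM = Mmat @ Mmat.T
    AM = Amat @ Mmat.T
    AA = Amat @ Amat.T
    out = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sum_n = float(MM[i, j])
            sum_d = float(AM[i, j] + AM[j, i] - 2.0 * AA[i, j])
            out[(ids[i], ids[j])] = (sum_d, sum_n)
    return out


# ---------------------------------------------------------------- file I/O

_COLUMNS = ["chrom", "pos", "derived", "total"]


def read_counts_tsv(path: str | Path, individual: str | None = None) -> SiteReadCounts:
    """Read a per-individual site-count TSV (gzip tolerated, header required)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    name = individual or path.name.removesuffix(".gz").removesuffix(".tsv")
    data = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        data[str(chrom)] = (
            sub["pos"].to_numpy(np.int64),
            sub["derived"].to_numpy(float),
            sub["total"].to_numpy(float),
        )
    return SiteReadCounts(name, data)


def write_counts_tsv(counts: SiteReadCounts, path: str | Path) -> None:
    path = Path(path)
    frames = []
    for chrom, (pos, der, tot) in counts.data.items():
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos,
                 "derived": np.asarray(der, dtype=np.int64),
                 "total": np.asarray(tot, dtype=np.int64)}
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_window_table(data: PairWindowData, grid: GenomeLayout, path: str | Path) -> None:
    """Write windowed (D, N) as TSV with 0-based half-open windows."""
    pd.DataFrame(
        {
            "chrom": grid.window_chrom,
            "start": grid.window_start,
            "end": grid.window_end,
            "D": data.D,
            "N": data.N,
        }
    ).to_csv(path, sep="\t", index=False)
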