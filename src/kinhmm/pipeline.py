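"""End-to-end orchestration on a directory of site-count tables.

Order of operations: read counts -> optional contamination correction ->
p0 estimation -> per-individual ROH HMM (when coverage allows) -> pairwise
ROH priors -> fit all relatedness models per pair -> classify -> write a
results table, per-pair IBD tracts (BED) and per-individual ROH
posteriors (bedGraph).  All inputs use 1-based positions; all outputs are
0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import PairResult, classify, fit_all
from .contamination import ContaminationParams, correct_pair_counts, correct_roh_counts
from .counts import (
    PairWindowData,
    SiteReadCounts,
    aggregate_pair_windows,
    estimate_p0,
    read_counts_tsv,
    within_individual_diffs,
)
from .emissions import EmissionParams
from .layout import DEFAULT_WINDOW_SIZE, GenomeLayout, build_window_grid
from .models import model_registry
from .roh import MIN_ROH_DEPTH, roh_em_fit, pair_roh_prior, uniform_roh_prior

logger = logging.getLogger("kinhmm")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    window_size: int = DEFAULT_WINDOW_SIZE
    p0: float | None = None  # override of the cohort-median estimate
    contamination_table: str | Path | None = None  # TSV: individual, C
    phi: float | None = None  # contaminant divergence, required with the table
    roh_mode: str = "auto"  # auto | off | file
    roh_file: str | Path | None = None  # bedGraph of P(hom) per window
    min_roh_depth: float = MIN_ROH_DEPTH
    cutoff: float = 1.0
    seed: int = 0
    mismatch_estimator: str = "unbiased"

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.roh_mode not in ("auto", "off", "file"):
            raise ValueError(f"unknown roh_mode {self.roh_mode!r}")


@dataclass
class PipelineResult:
    config: RunConfig
    grid: GenomeLayout
    p0: float
    results: dict[tuple[str, str], PairResult]
    roh_posteriors: dict[str, np.ndarray] = field(default_factory=dict)
    ibd_paths: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _infer_layout(counts: list[SiteReadCounts], window_size: int) -> GenomeLayout:
    """Window grid from the maximum observed position per chromosome."""
    chroms: dict[str, int] = {}
    for c in counts:
        for chrom, (pos, _, _) in c.data.items():
            chroms[chrom] = max(chroms.get(chrom, 0), int(pos[-1]) if len(pos) else 1)
    return build_window_grid(list(chroms.items()), window_size)


def _read_contamination(path: str | Path, phi: float) -> ContaminationParams:
    df = pd.read_csv(path, sep="\t")
    if not {"individual", "C"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'individual' and 'C'")
    return ContaminationParams(dict(zip(df["individual"].astype(str), df["C"])), phi)


def run_pipeline(
    config: RunConfig, counts: list[SiteReadCounts] | None = None
) -> PipelineResult:
    """Classify every pair in a cohort of site-count tables."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if counts is None:
        files = sorted(Path(config.input_dir).glob("*.tsv")) + sorted(
            Path(config.input_dir).glob("*.tsv.gz")
        )
        counts = [read_counts_tsv(f) for f in files]
    if len(counts) < 2:
        raise ValueError("need at least two individuals")
    ids = [c.individual for c in counts]
    grid = _infer_layout(counts, config.window_size)
    chrom_slices = grid.chrom_slices()

    contam = None
    if config.contamination_table is not None:
        if config.phi is None:
            raise ValueError("phi is required with a contamination table")
        contam = _read_contamination(config.contamination_table, config.phi)

    # pairwise windowed differences (contamination-corrected when configured)
    pair_data: dict[tuple[str, str], PairWindowData] = {}
    for a, b in combinations(counts, 2):
        d = aggregate_pair_windows(a, b, grid)
        if contam is not None:
            d = correct_pair_counts(d, contam)
        pair_data[(a.individual, b.individual)] = d

    p0 = config.p0 if config.p0 is not None else estimate_p0(list(pair_data.values()))
    logger.info("p0 = %.5f (%s)", p0, "override" if config.p0 is not None else "cohort median")
    params = EmissionParams(p0)

    # per-individual ROH posteriors
    roh_posteriors: dict[str, np.ndarray] = {}
    if config.roh_mode == "file":
        roh_posteriors = _read_roh_file(config.roh_file, grid)
    elif config.roh_mode == "auto":
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed).spawn(1)[0])
        for c in counts:
            inp = within_individual_diffs(c, grid, estimator=config.mismatch_estimator)
            if contam is not None:
                inp = correct_roh_counts(inp, contam)
            if inp.mean_depth < config.min_roh_depth or inp.M.sum() <= 0:
                logger.info("%s: coverage below %.2fx, skipping ROH HMM",
                            c.individual, config.min_roh_depth)
                continue
            fit = roh_em_fit(inp, p0, chrom_slices, seed=rng)
            roh_posteriors[c.individual] = fit.q

    results: dict[tuple[str, str], PairResult] = {}
    ibd_paths: dict[tuple[str, str], np.ndarray] = {}
    registry = model_registry(b=config.window_size)
    for k, (pair, data) in enumerate(pair_data.items()):
        qi = roh_posteriors.get(pair[0])
        qj = roh_posteriors.get(pair[1])
        if qi is None and qj is None:
            h = uniform_roh_prior(grid.L)
        else:
            zero = np.zeros(grid.L)
            h = pair_roh_prior(qi if qi is not None else zero,
                               qj if qj is not None else zero)
        try:
            fits = fit_all(data, h, registry, params, chrom_slices,
                           seed=config.seed + 1000 * k)
        except ValueError as err:
            logger.warning("pair %s: %s", pair, err)
            continue
        res = classify(fits, pair=pair, cutoff=config.cutoff)
        results[pair] = res
        ibd_paths[pair] = fits[res.best_case].viterbi_path
        logger.info("%s-%s: %s (dLL=%.2f)", pair[0], pair[1], res.best_group, res.delta_ll)

    _write_outputs(config, grid, p0, results, ibd_paths, roh_posteriors, out_dir)
    return PipelineResult(config, grid, p0, results, roh_posteriors, ibd_paths)


def _read_roh_file(path: str | Path | None, grid: GenomeLayout) -> dict[str, np.ndarray]:
    """User-supplied per-window P(hom): TSV individual, chrom, start, end, q."""
    if path is None:
        raise ValueError("roh_mode='file' requires roh_file")
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for ind, sub in df.groupby("individual"):
        q = np.zeros(grid.L)
        for chrom, csub in sub.groupby("chrom"):
            idx = grid.window_index(str(chrom), csub["start"].to_numpy())
            q[idx] = csub["q"].to_numpy(float)
        out[str(ind)] = q
    return out


def _write_outputs(config, grid, p0, results, ibd_paths, roh_posteriors, out_dir: Path):
    rows = []
    for pair, r in results.items():
        row = {
            "pair_i": pair[0], "pair_j": pair[1],
            "best_group": r.best_group, "best_case": r.best_case,
            "second_case": r.second_case,
            "delta_LL": r.delta_ll, "delta_LL_fine": r.delta_ll_fine,
            "confident": r.confident,
            "k0": r.k_hat[0], "k1": r.k_hat[1], "k2": r.k_hat[2], "r": r.r_hat,
        }
        row.update({f"loglik_{c}": ll for c, ll in r.logliks.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "results.tsv", sep="\t", index=False)

    with open(out_dir / "ibd_tracts.bed", "w") as fh:
        for pair, path in ibd_paths.items():
            for w in range(grid.L):
                fh.write(
                    f"{grid.window_chrom[w]}\t{grid.window_start[w]}\t"
                    f"{grid.window_end[w]}\t{pair[0]}|{pair[1]}|IBD{path[w]}\n"
                )
    with open(out_dir / "roh_posterior.bedgraph", "w") as fh:
        for ind, q in roh_posteriors.items():
            for w in range(grid.L):
                fh.write(
                    f"{grid.window_chrom[w]}\t{grid.window_start[w]}\t"
                    f"{grid.window_end[w]}\t{q[w]:.4f}\t{ind}\n"
                )
    cfg = {k: str(v) for k, v in vars(config).items()}
    log = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12],
        "p0": p0,
        "delta_LL": {f"{a}-{b}": r.delta_ll for (a, b), r in results.items()},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))


def validate_inputs(directory: str | Path) -> list[dict[str, str]]:
    """Schema and consistency report for a directory of count tables."""
    issues: list[dict[str, str]] = []
    files = sorted(Path(directory).glob("*.tsv")) + sorted(Path(directory).glob("*.tsv.gz"))
    if len(files) < 2:
        issues.append({"level": "error", "file": str(directory),
                       "message": "fewer than two count tables found"})
    universe: dict[str, int] | None = None
    for f in files:
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as err:  # noqa: BLE001
            issues.append({"level": "error", "file": f.name, "message": str(err)})
            continue
        missing = [c for c in ("chrom", "pos", "derived", "total") if c not in df.columns]
        if missing:
            issues.append({"level": "error", "file": f.name,
                           "message": f"missing columns {missing}"})
            continue
        bad = df.index[df["derived"] > df["total"]]
        if len(bad):
            issues.append({"level": "error", "file": f.name,
                           "message": f"derived > total at line {int(bad[0]) + 2}"})
        for chrom, sub in df.groupby("chrom"):
            if not sub["pos"].is_monotonic_increasing:
                issues.append({"level": "warning", "file": f.name,
                               "message": f"{chrom}: unsorted positions (will be auto-sorted)"})
        sizes = dict(df.groupby("chrom")["pos"].count())
        if universe is None:
            universe = sizes
        elif sizes != universe:
            issues.append({"level": "warning", "file": f.name,
                           "message": "site universe differs from first table"})
        n = len(df)
        if n < 1000:
            issues.append({"level": "warning", "file": f.name,
                           "message": f"only {n} sites"})
    return issues
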