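"""Benchmark pipeline: input -> mask -> impute -> NJ tree -> RF rate.

Orchestrates the full experimental loop over replicates: take a complete
distance matrix (from simulation, from sequences, or from a file), delete
entries with the direct mechanism, impute with each configured method,
build a neighbor-joining tree from the completed matrix, and score it by
the normalized Robinson-Foulds rate against a reference tree (the model
tree for synthetic input; the NJ tree on the complete matrix otherwise).

The per-replicate rows and mean +/- standard error summaries are plain
pandas DataFrames / TSV files; every row carries the seeds that produced
it, so any line of the report can be regenerated in isolation.
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ae import AEConfig, ae_impute_with_model
from .distances import Alignment, alignment_to_matrix
from .matrix import MaskedDistanceMatrix, read_matrix, write_matrix
from .mf import MFConfig, mf_impute_with_factors
from .missingness import delete_random_entries
from .synthetic import SimConfig, random_tree, perturbed_matrix, simulate_alignment
from .trees import PhyloTree, nj_tree, rf_rate, write_newick

__all__ = ["PipelineConfig", "run_pipeline", "mean_fill_impute", "summarize"]

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "replicate",
    "method",
    "n_missing",
    "rf_rate",
    "iterations",
    "final_loss",
    "mask_seed",
    "impute_seed",
]


def mean_fill_impute(m: MaskedDistanceMatrix) -> MaskedDistanceMatrix:
    """Baseline imputer: fill every missing pair with the mean observed
    off-diagonal distance.  Useful as a floor for judging real imputers."""
    if m.is_complete:
        return m.copy()
    if m.observed_count == 0:
        raise ValueError("matrix has no observed off-diagonal entries")
    obs = [m.values[i, j] for i, j in m.observed_pairs()]
    fill = float(np.mean(obs))
    values = m.values.copy()
    for i, j in m.missing_pairs():
        values[i, j] = values[j, i] = fill
    return MaskedDistanceMatrix(m.labels, values)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one benchmark run.

    ``input_kind`` is ``synthetic`` (matrix from a random model tree,
    either its exact additive matrix or distances re-estimated from
    simulated sequences), ``sequences`` (FASTA alignment) or ``matrix``
    (distance-matrix file; must be complete so entries can be deleted and
    scored).
    """

    input_kind: str = "synthetic"
    # synthetic input
    sim: SimConfig = field(default_factory=SimConfig)
    synthetic_source: str = "additive"  # "additive" | "sequences"
    # file input
    fasta: Optional[str] = None
    matrix_path: Optional[str] = None
    distance_model: str = "tn93"
    # missingness (direct mechanism)
    n_missing: tuple[int, ...] = (5,)
    # imputation
    methods: tuple[str, ...] = ("mf", "ae")
    mf: MFConfig = field(default_factory=MFConfig)
    ae: AEConfig = field(default_factory=AEConfig)
    # run control
    replicates: int = 10
    seed: int = 1
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.input_kind not in ("synthetic", "sequences", "matrix"):
            raise ValueError(f"unknown input kind {self.input_kind!r}")
        if self.synthetic_source not in ("additive", "sequences"):
            raise ValueError(f"unknown synthetic source {self.synthetic_source!r}")
        unknown = set(self.methods) - {"mf", "ae", "mean"}
        if unknown:
            raise ValueError(f"unknown imputation methods: {sorted(unknown)}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        kw: dict = {}
        inp = raw.get("input", {})
        kw["input_kind"] = inp.get("kind", "synthetic")
        kw["fasta"] = inp.get("fasta")
        kw["matrix_path"] = inp.get("matrix")
        kw["distance_model"] = inp.get("model", "tn93")
        kw["synthetic_source"] = raw.get("synthetic", {}).pop("source", "additive")
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if "gene_lengths" in syn:
                syn["gene_lengths"] = tuple(syn["gene_lengths"])
            if "base_freqs" in syn:
                syn["base_freqs"] = tuple(syn["base_freqs"])
            kw["sim"] = SimConfig(**syn)
        miss = raw.get("missingness", {})
        kw["n_missing"] = tuple(miss.get("counts", [5]))
        imp = raw.get("imputation", {})
        kw["methods"] = tuple(imp.get("methods", ["mf", "ae"]))
        if "mf" in imp:
            mf_kw = dict(imp["mf"])
            if "hidden_sizes" in mf_kw:
                raise ValueError("hidden_sizes belongs to the ae table")
            kw["mf"] = MFConfig(**mf_kw)
        if "ae" in imp:
            ae_kw = dict(imp["ae"])
            if "hidden_sizes" in ae_kw:
                ae_kw["hidden_sizes"] = tuple(ae_kw["hidden_sizes"])
            kw["ae"] = AEConfig(**ae_kw)
        run = raw.get("run", {})
        kw["replicates"] = run.get("replicates", 10)
        kw["seed"] = run.get("seed", 1)
        kw["outdir"] = run.get("outdir")
        return cls(**kw)


def _replicate_input(
    cfg: PipelineConfig, rep_seed: int
) -> tuple[MaskedDistanceMatrix, PhyloTree]:
    """Complete matrix + reference tree for one replicate."""
    if cfg.input_kind == "synthetic":
        sim = SimConfig(
            **{**cfg.sim.__dict__, "seed": rep_seed}
        )
        tree = random_tree(sim)
        if cfg.synthetic_source == "sequences":
            aln, _ = simulate_alignment(tree, sim)
            full = alignment_to_matrix(aln, model=cfg.distance_model)
            if not full.is_complete:
                raise RuntimeError("simulated alignment gave undefined distances")
        else:
            full = perturbed_matrix(tree, cfg.sim.sigma, rep_seed)
        return full, tree
    if cfg.input_kind == "sequences":
        aln = Alignment.from_fasta(cfg.fasta)
        full = alignment_to_matrix(aln, model=cfg.distance_model)
    else:
        full = read_matrix(cfg.matrix_path)
    if not full.is_complete:
        raise ValueError("input matrix/alignment yields missing entries; "
                         "the benchmark needs a complete reference")
    return full, nj_tree(full)


def _impute(method: str, masked: MaskedDistanceMatrix, cfg: PipelineConfig,
            impute_seed: int):
    """Run one imputer; returns (completed matrix, iterations, final loss)."""
    if method == "mf":
        mf_cfg = MFConfig(**{**cfg.mf.__dict__, "seed": impute_seed})
        imputed, factors = mf_impute_with_factors(masked, mf_cfg)
        if factors is None:
            return imputed, 0, 0.0
        return imputed, factors.n_iter, float(factors.error_trace[-1])
    if method == "ae":
        ae_cfg = AEConfig(**{**cfg.ae.__dict__, "seed": impute_seed})
        imputed, model = ae_impute_with_model(masked, ae_cfg)
        if model is None:
            return imputed, 0, 0.0
        return imputed, model.n_iter, float(model.loss_trace[-1])
    return mean_fill_impute(masked), 0, float("nan")


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run the replicate loop and return the per-replicate report.

    Per-replicate seeds are derived as ``cfg.seed + replicate`` (matrix
    generation and entry deletion) and ``cfg.seed + 1000 + replicate``
    (imputer initialization).  A failing stage aborts that replicate/method
    combination, is logged, and appears in the report with NaN RF; the run
    continues.
    """
    rows = []
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    for rep in range(cfg.replicates):
        rep_seed = cfg.seed + rep
        impute_seed = cfg.seed + 1000 + rep
        t0 = time.perf_counter()
        full, ref_tree = _replicate_input(cfg, rep_seed)
        log.info("replicate %d: input ready in %.2fs", rep, time.perf_counter() - t0)
        if outdir:
            write_newick(ref_tree, outdir / f"rep{rep}_reference.nwk")
        for m_missing in cfg.n_missing:
            masked = delete_random_entries(full, m_missing, rep_seed)
            if outdir:
                write_matrix(masked, outdir / f"rep{rep}_m{m_missing}_masked.phy")
            for method in cfg.methods:
                t0 = time.perf_counter()
                try:
                    imputed, iters, loss = _impute(method, masked, cfg, impute_seed)
                    tree = nj_tree(imputed)
                    rf = rf_rate(ref_tree, tree)
                    if outdir:
                        write_matrix(
                            imputed, outdir / f"rep{rep}_m{m_missing}_{method}.phy"
                        )
                        write_newick(
                            tree, outdir / f"rep{rep}_m{m_missing}_{method}.nwk"
                        )
                except Exception:
                    log.exception(
                        "replicate %d method %s m=%d failed", rep, method, m_missing
                    )
                    rf, iters, loss = float("nan"), 0, float("nan")
                log.info(
                    "replicate %d method %s m=%d: RF=%.4f in %.2fs",
                    rep, method, m_missing, rf, time.perf_counter() - t0,
                )
                rows.append(
                    {
                        "replicate": rep,
                        "method": method,
                        "n_missing": m_missing,
                        "rf_rate": rf,
                        "iterations": iters,
                        "final_loss": loss,
                        "mask_seed": rep_seed,
                        "impute_seed": impute_seed,
                    }
                )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if outdir:
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        summarize(report).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return report


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Mean RF rate and standard error (sample SD / sqrt(r)) per condition."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        r = len(g)
        sd = g["rf_rate"].std(ddof=1) if r > 1 else 0.0
        return pd.Series(
            {
                "replicates": r,
                "mean_rf": g["rf_rate"].mean(),
                "se_rf": sd / np.sqrt(r) if r > 1 else 0.0,
            }
        )

    out = (
        report.groupby(["method", "n_missing"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["replicates"] = out["replicates"].astype(int)
    return out
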