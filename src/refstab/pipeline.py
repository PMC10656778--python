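"""End-to-end orchestration: simulate/load -> screen -> efficiency -> stability
(overall and per-condition subsets) -> consensus -> normalization, with a JSON
run manifest recording inputs, seeds and per-stage outputs.

Stages whose inputs are absent are skipped and logged; any stage failure aborts
the run with the failing stage named. Re-running with identical inputs and seed
reproduces byte-identical CSV outputs (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidate_screening import screen_candidates
from .errors import RefstabError
from .normalization import expression_profile
from .rank_aggregation import aggregate_ranks
from .stability_methods import METHODS, run_all_methods
from .standard_curve import fit_standard_curve
from .synthetic_data import SimSpec, simulate_ct, simulate_dilution, simulate_fpkm
from .tabular_io import (
    RunConfig,
    collapse_technical_replicates,
    read_ct_table,
    read_expression_table,
    write_matrix,
    write_table,
)

log = logging.getLogger("refstab")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[refstab:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config: dict
    seed: int
    package_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {status, outputs: {path: rows}}
    started: str = ""
    finished: str = ""

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: RunManifest, stage: str, outputs: dict[Path, int], status: str = "ok") -> None:
    manifest.stages[stage] = {
        "status": status,
        "outputs": {str(p): int(n) for p, n in outputs.items()},
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full workflow described by ``config``; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed)
    manifest.started = time.strftime("%Y-%m-%dT%H:%M:%S")

    fpkm_path = outdir / "fpkm.csv"
    ct_path = outdir / "ct.csv"
    meta_path = outdir / "meta.csv"

    # --- stage: simulate -------------------------------------------------
    if config.simulate:
        stage = "simulate"
        try:
            rng = np.random.default_rng(config.seed)
            expr, stable = simulate_fpkm(500, 42, 30, seed=config.seed)
            n_genes = 10
            mu = rng.uniform(18.0, 30.0, n_genes)
            tau = np.full(n_genes, 0.05)
            tau[-1] = 2.0
            spec = SimSpec(mu=mu, tau=tau, n_groups=5, n_bio_reps=3,
                           loading_sd=1.0, noise_sd=0.2, seed=config.seed)
            ct, truth = simulate_ct(spec)
            write_matrix(expr.data, fpkm_path)
            write_matrix(ct.data, ct_path)
            ct.meta.to_csv(meta_path, index_label="sample_id")
            write_table(truth, outdir / "truth.csv")
            dilution_paths = []
            for gid, eff in zip(ct.gene_ids[:3], (94.08, 100.0, 104.87)):
                series = simulate_dilution(gid, eff, n_points=5, noise_sd=0.05,
                                           seed=int(rng.integers(2**31)))
                dpath = outdir / f"dilution_{gid}.csv"
                write_table(pd.DataFrame(series.points, columns=["log10_amount", "ct"]), dpath, 6)
                dilution_paths.append(dpath)
            _record(manifest, stage, {fpkm_path: 500, ct_path: n_genes, meta_path: len(ct.sample_ids),
                                      **{p: 5 for p in dilution_paths}})
            _stage_log(stage, f"wrote simulated inputs to {outdir}")
        except Exception as exc:
            raise RefstabError(f"stage 'simulate' failed: {exc}") from exc

    for p in (fpkm_path, ct_path, meta_path):
        if p.exists():
            manifest.input_digests[str(p)] = _digest(p)

    # --- stage: screen ---------------------------------------------------
    if fpkm_path.exists():
        stage = "screen"
        try:
            expr = read_expression_table(fpkm_path)
            report = screen_candidates(expr, config.mv_min, config.top_n_sd,
                                       config.cv_max, config.mfc_max)
            out = outdir / "screening.csv"
            write_table(report, out)
            _record(manifest, stage, {out: len(report)})
            _stage_log(stage, f"{int(report['passes'].sum())} of {len(report)} genes pass")
        except Exception as exc:
            raise RefstabError(f"stage 'screen' failed: {exc}") from exc
    else:
        _record(manifest, "screen", {}, status="skipped (no fpkm.csv)")
        _stage_log("screen", "skipped: no FPKM table")

    # --- stage: efficiency ----------------------------------------------
    dilution_files = sorted(outdir.glob("dilution_*.csv"))
    if dilution_files:
        stage = "efficiency"
        try:
            rows = []
            for dpath in dilution_files:
                gid = dpath.stem.removeprefix("dilution_")
                pts = pd.read_csv(dpath)
                from .tabular_io import DilutionSeries

                series = DilutionSeries(gid, list(zip(pts["log10_amount"], pts["ct"])))
                fit = fit_standard_curve(series)
                rows.append({"gene_id": gid, "slope": fit.slope, "intercept": fit.intercept,
                             "r_squared": fit.r_squared, "efficiency_pct": fit.efficiency_pct})
            out = outdir / "curves.csv"
            write_table(pd.DataFrame(rows), out)
            _record(manifest, stage, {out: len(rows)})
            _stage_log(stage, f"fitted {len(rows)} standard curves")
        except Exception as exc:
            raise RefstabError(f"stage 'efficiency' failed: {exc}") from exc
    else:
        _record(manifest, "efficiency", {}, status="skipped (no dilution series)")
        _stage_log("efficiency", "skipped: no dilution series found")

    # --- stage: stability + consensus (overall and per subset) -----------
    consensus_paths: dict[str, Path] = {}
    if ct_path.exists() and meta_path.exists():
        stage = "stability"
        try:
            ct = collapse_technical_replicates(read_ct_table(ct_path, meta_path))
            partitions: dict[str, list[str] | None] = {"all": None, **config.subsets}
            outputs: dict[Path, int] = {}
            for name, groups in partitions.items():
                sub = ct if groups is None else ct.subset_groups(list(groups))
                tables = run_all_methods(sub, METHODS, config.bestkeeper_variant)
                subdir = outdir / ("stability" if name == "all" else f"stability_{name}")
                subdir.mkdir(exist_ok=True)
                for m, t in tables.items():
                    p = subdir / f"{m}.csv"
                    write_table(t.table, p)
                    outputs[p] = len(t.table)
                pv = tables["genorm"].extras["pairwise_variation"]
                pvp = subdir / "genorm_pairwise_variation.csv"
                pv.rename("V").to_frame().to_csv(pvp, float_format="%.4f", index_label="n")
                outputs[pvp] = len(pv)
                consensus = aggregate_ranks(list(tables.values()))
                cp = subdir / "consensus.csv"
                write_table(consensus, cp)
                outputs[cp] = len(consensus)
                consensus_paths[name] = cp
            _record(manifest, stage, outputs)
            _stage_log(stage, f"ran 4 methods on {len(partitions)} sample partition(s)")
        except Exception as exc:
            raise RefstabError(f"stage 'stability' failed: {exc}") from exc
    else:
        _record(manifest, "stability", {}, status="skipped (no ct/meta)")
        _stage_log("stability", "skipped: no Ct table")

    # --- stage: normalize -------------------------------------------------
    if config.targets and config.references and config.control_group and ct_path.exists():
        stage = "normalize"
        try:
            ct = collapse_technical_replicates(read_ct_table(ct_path, meta_path))
            bad = config.bad_reference or config.references[-1]
            profile = expression_profile(ct, list(config.targets), list(config.references),
                                         bad, config.control_group)
            out = outdir / "expression.csv"
            write_table(profile, out)
            _record(manifest, stage, {out: len(profile)})
            _stage_log(stage, f"normalized {len(config.targets)} target gene(s)")
        except Exception as exc:
            raise RefstabError(f"stage 'normalize' failed: {exc}") from exc
    else:
        _record(manifest, "normalize", {}, status="skipped (no targets configured)")
        _stage_log("normalize", "skipped: no targets/references configured")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest
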