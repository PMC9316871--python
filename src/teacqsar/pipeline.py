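"""End-to-end run orchestration and report assembly.

Ties the stages together in the study's order — descriptors, degenerate
filtering, activity-ranked splitting, normalization, GA-MLR ladder with
QUIK filtering, internal/external validation, applicability domain — and
writes a reproducible report bundle (CSV/JSON plus a plain-text log).  All
randomness flows from the single config seed; every artifact carries the
config hash.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ad, validation
from .data import DescriptorTable, band_counts, filter_descriptors, normalize, \
    rational_split
from .ga import GAConfig, build_model_ladder
from .mlr import fit_statistics
from .synthetic import make_paper_like_dataset

__all__ = ["RunConfig", "run_pipeline", "bands_report"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable so a run can be
    reproduced from its archived config and seed."""

    input_csv: str | None = None     # descriptor CSV with activity column
    simulate: bool = False           # generate the study-scale dataset instead
    n_test: int = 14
    model_sizes: list[int] = field(default_factory=lambda: list(range(1, 9)))
    population_size: int = 200
    generations: int = 2000
    mutation_probability: float = 0.20
    fitness_metric: str = "q2_loo"
    elitism: int = 2
    quik_delta: float = 0.05
    cross_r_limit: float = 0.7
    variance_tol: float = 0.0
    pair_r_max: float = 0.95
    lmo_fraction: float = 0.3
    lmo_iterations: int = 100
    yscrambling_permutations: int = 100
    seed: int = 0
    output_dir: str = "teacqsar_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls(**payload)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def bands_report(teacs) -> dict:
    """Band counts with whole-number percentages over a compound panel."""
    teacs = list(teacs)
    if not teacs:
        raise ValueError("empty compound panel")
    counts = band_counts(teacs)
    n = len(teacs)
    percentages = {band: round(100.0 * c / n) for band, c in counts.items()}
    return {
        "n_compounds": n,
        "counts": counts,
        "percentages": percentages,
        "share_above_low_percent": round(100.0 * (counts["mid"] + counts["high"]) / n),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns a manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    chash = config.config_hash()

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    log(f"run start seed={config.seed} config_hash={chash}")
    try:
        if config.simulate:
            dataset = make_paper_like_dataset(seed=config.seed)
            table = dataset.descriptor_table
            log("stage simulate: study-scale synthetic dataset generated")
        elif config.input_csv:
            table = DescriptorTable.from_csv(config.input_csv)
            log(f"stage load: {config.input_csv}")
        else:
            raise ValueError("config needs input_csv or simulate=true")
        if table.activity is None:
            raise ValueError("input table has no 'activity' column")

        table, removal_log = filter_descriptors(
            table, config.variance_tol, config.pair_r_max)
        log(f"stage filter: {len(removal_log)} descriptors removed")

        split = rational_split(table.activity, config.n_test, seed=config.seed)
        log(f"stage split: {len(split.train_ids)} train / {len(split.test_ids)} test")

        train = table.subset_rows(split.train_ids)
        test = table.subset_rows(split.test_ids)
        train_norm, params, _ = normalize(train)
        test_norm, _, oor = normalize(test, params=params)
        log(f"stage normalize: {int(oor.to_numpy().sum())} test values out of [0,1]")

        ga_cfg = GAConfig(
            model_size=max(config.model_sizes),
            population_size=config.population_size,
            generations=config.generations,
            mutation_probability=config.mutation_probability,
            fitness_metric=config.fitness_metric,
            elitism=config.elitism,
            quik_delta=config.quik_delta,
            cross_r_limit=config.cross_r_limit,
            seed=config.seed,
        )
        y_tr = train_norm.activity.to_numpy(dtype=float)
        y_te = test_norm.activity.to_numpy(dtype=float)
        ladder, stats_table = build_model_ladder(
            train_norm.data, y_tr, config.model_sizes, ga_cfg)
        log(f"stage select: ladder sizes {sorted(ladder)}")

        reports = {}
        train_mean = float(y_tr.mean())
        train_tss_per_n = float(((y_tr - train_mean) ** 2).sum() / len(y_tr))
        for size, candidate in ladder.items():
            cols_tr = train_norm.data[list(candidate.descriptor_names)]
            cols_te = test_norm.data[list(candidate.descriptor_names)]
            fit = fit_statistics(candidate.fitted, cols_tr, y_tr)
            internal = validation.loo_cv(cols_tr, y_tr)
            external = validation.external_validation(
                candidate.fitted, cols_te, y_te, train_mean, train_tss_per_n)
            lmo = validation.lmo_cv(cols_tr, y_tr, config.lmo_fraction,
                                    config.lmo_iterations, seed=config.seed)
            yscr = validation.y_scramble(cols_tr, y_tr,
                                         config.yscrambling_permutations,
                                         seed=config.seed)
            flags = validation.acceptability_check(fit, internal, external, yscr)
            report = validation.validation_report(
                fit, internal, external,
                kxx=candidate.k.kxx if candidate.k else None,
                delta_k=candidate.k.delta_k if candidate.k else None)
            report.update({
                "Q2_LMO": lmo.q2_lmo,
                "R2_yscr_mean": yscr.mean_r2,
                "Q2_yscr_mean": yscr.mean_q2,
                "descriptors": list(candidate.descriptor_names),
                "acceptable": dataclasses.asdict(flags),
                "config_hash": chash,
            })
            for key, value in report.items():
                if isinstance(value, (np.floating, np.bool_)):
                    report[key] = value.item()
            reports[size] = report
            stats_table.loc["Q2_LMO", size] = lmo.q2_lmo
            stats_table.loc["RMSE_ext", size] = external.rmse_ext
            stats_table.loc["MAE_ext", size] = external.mae_ext
            stats_table.loc["PRESS_ext", size] = external.press_ext
            stats_table.loc["R2_ext", size] = external.r2_ext
            stats_table.loc["Q2_F1", size] = external.q2_f1
            stats_table.loc["Q2_F2", size] = external.q2_f2
            stats_table.loc["Q2_F3", size] = external.q2_f3
            stats_table.loc["CCC_ext", size] = external.ccc_ext
        log("stage validate: internal/external/Y-scrambling done")

        best_size = max(reports, key=lambda s: reports[s]["Q2_F2"])
        best = ladder[best_size]
        report_ad = ad.williams_report(
            best.fitted,
            train_norm.data[list(best.descriptor_names)], y_tr,
            test_norm.data[list(best.descriptor_names)], y_te)
        log(f"stage ad: best size {best_size}, "
            f"{len(report_ad.x_outliers)} X-outliers, "
            f"{len(report_ad.y_outliers)} Y-outliers")

        bands = bands_report(table.activity)
        bands["config_hash"] = chash

        # --- write the bundle ---
        stats_path = out_dir / "statistics.csv"
        with open(stats_path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            stats_table.to_csv(fh, float_format="%.6g")
        with open(out_dir / "validation.json", "w") as fh:
            json.dump(reports, fh, indent=1)
        report_ad.to_csv(out_dir / "applicability_domain.csv")
        with open(out_dir / "ad_summary.json", "w") as fh:
            json.dump({**report_ad.summary(), "best_size": best_size,
                       "config_hash": chash}, fh, indent=1)
        with open(out_dir / "bands.json", "w") as fh:
            json.dump(bands, fh, indent=1)
        for size, candidate in ladder.items():
            candidate.fitted.to_json(out_dir / f"model_size{size}.json")
        split.to_json(out_dir / "split.json")
        config.to_file(out_dir / "config.yaml")
        log("run complete")
    finally:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "output_dir": str(out_dir),
        "config_hash": chash,
        "best_size": best_size,
        "reports": reports,
    }
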