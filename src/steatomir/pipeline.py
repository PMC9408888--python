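"""End-to-end orchestration: simulate or load a paired cohort, run both
tissue arms (filters, normalization, screening, full PLS model, RFE),
intersect the per-tissue panels, rank them biologically, and exhaustively
search 2-3-miRNA serum models.  Every output is a plain-text table and the
run manifest records the config, seed and content hashes, so a run is
reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .association import pca_scores, pearson_screen
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .matrix import CountMatrix, PhenotypeVector, ValidationError
from .pls import PLS1Model
from .preprocess import common_feature_set, normalize
from .ranking import DEFAULT_RULES, PenaltyRules, build_records, panel_to_frame, rank_panel
from .selection import combinations_to_frame, exhaustive_search, intersect_panels, optimal_subset, rfe

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("steatomir")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Full-run settings; defaults mirror the reference study configuration."""

    mode: str = "synthetic"  # "synthetic" | "files"
    liver_counts: Optional[str] = None
    serum_counts: Optional[str] = None
    liver_phenotype: Optional[str] = None
    serum_phenotype: Optional[str] = None
    annotation: Optional[str] = None
    liver_detection_fraction: float = 0.90
    serum_detection_fraction: float = 0.825
    alpha: float = 0.05
    target_subset_size: int = 50
    permutations: int = 500
    subset_sizes: tuple[int, ...] = (2, 3)
    seed: int = 0
    outdir: str = "steatomir_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        for frac in (self.liver_detection_fraction, self.serum_detection_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("detection fractions must be in [0, 1]")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if not set(self.subset_sizes) <= {2, 3}:
            raise ValidationError("subset_sizes must be a subset of {2, 3}")
        if self.mode == "files":
            needed = {
                "liver_counts": self.liver_counts,
                "serum_counts": self.serum_counts,
                "liver_phenotype": self.liver_phenotype,
                "serum_phenotype": self.serum_phenotype,
                "annotation": self.annotation,
            }
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ValidationError(f"file mode requires paths for: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        if "subset_sizes" in raw:
            raw["subset_sizes"] = tuple(raw["subset_sizes"])
        cfg = cls(cohort=cohort, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subset_sizes"] = list(self.subset_sizes)
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent substreams derived from the single run seed."""
    state = np.random.SeedSequence(seed).generate_state(3)
    names = ["cohort", "perm_liver", "perm_serum"]
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_inputs(config: PipelineConfig, seeds: dict):
    if config.mode == "synthetic":
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
        cohort = generate_cohort(cohort_cfg)
        return (
            cohort.liver_counts,
            cohort.serum_counts,
            cohort.liver_tg,
            cohort.serum_fat,
            cohort.annotation,
            cohort,
        )
    liver = CountMatrix.from_tsv(config.liver_counts)
    serum = CountMatrix.from_tsv(config.serum_counts)
    liver_ph = PhenotypeVector.from_csv(config.liver_phenotype)
    serum_ph = PhenotypeVector.from_csv(config.serum_phenotype)
    annotation = pd.read_csv(config.annotation, sep="\t")
    return liver, serum, liver_ph, serum_ph, annotation, None


def run_pipeline(config: PipelineConfig, rules: PenaltyRules = DEFAULT_RULES) -> dict:
    """Execute the full discovery pipeline; returns the report bundle
    (in-memory results plus the paths of everything written)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    bundle: dict = {"outdir": str(outdir)}
    stage = "setup"

    def _log(stage: str, t0: float, **info) -> None:
        extras = " ".join(f"{k}={v}" for k, v in info.items())
        logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)

    try:
        stage = "load"
        t0 = time.perf_counter()
        liver, serum, liver_ph, serum_ph, annotation, cohort = _load_inputs(config, seeds)
        _log(stage, t0, liver=liver.shape, serum=serum.shape)

        stage = "filter"
        t0 = time.perf_counter()
        retained = common_feature_set(
            liver, serum, config.liver_detection_fraction, config.serum_detection_fraction
        )
        if not retained:
            raise ValidationError("no miRNAs survive the clean-up filters")
        (outdir / "filtered_features.txt").write_text("\n".join(retained) + "\n")
        liver_f, serum_f = liver.subset(retained), serum.subset(retained)
        _log(stage, t0, retained=len(retained))

        stage = "normalize"
        t0 = time.perf_counter()
        liver_norm, serum_norm = normalize(liver_f), normalize(serum_f)
        for name, norm in (("liver", liver_norm), ("serum", serum_norm)):
            norm.to_tsv(outdir / f"{name}_normalized.tsv")
            _write_json(
                outdir / f"{name}_size_factors.json",
                {s: float(f) for s, f in norm.size_factors.items()},
            )
        _log(stage, t0)

        stage = "correlation"
        t0 = time.perf_counter()
        liver_corr = pearson_screen(liver_norm, liver_ph, config.alpha)
        serum_corr = pearson_screen(serum_norm, serum_ph, config.alpha)
        for name, corr in (("liver", liver_corr), ("serum", serum_corr)):
            corr.to_csv(outdir / f"{name}_correlations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        _log(stage, t0, liver_sig=int(liver_corr["significant"].sum()),
             serum_sig=int(serum_corr["significant"].sum()))

        stage = "pca"
        t0 = time.perf_counter()
        pca = {}
        for name, norm in (("liver", liver_norm), ("serum", serum_norm)):
            res = pca_scores(norm, n_components=2)
            pca[name] = res
            with open(outdir / f"{name}_pca_scores.tsv", "w") as fh:
                frac = ",".join(f"{f:.6f}" for f in res.explained_variance_fraction)
                fh.write(f"# explained_variance_fraction\t{frac}\n")
                res.scores.to_csv(fh, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
        _log(stage, t0, liver_pc1=round(float(pca["liver"].explained_variance_fraction[0]), 3))

        stage = "full_model"
        t0 = time.perf_counter()
        arms = {}
        for name, norm, ph, perm_seed in (
            ("liver", liver_norm, liver_ph, seeds["perm_liver"]),
            ("serum", serum_norm, serum_ph, seeds["perm_serum"]),
        ):
            X = norm.values.T  # samples x features
            y = ph.align(norm.sample_ids)
            res = PLS1Model(y, X).fit()
            perm = res.permutation_test(B=config.permutations, seed=perm_seed)
            arms[name] = {"X": X, "y": y, "results": res, "perm": perm}
            _write_json(
                outdir / f"{name}_model_summary.json",
                {
                    "n_components": res.n_components,
                    "rmsecv": res.rmsecv,
                    "permutation_p": perm.p_value,
                    "permutations": perm.B,
                    "regression_vector_autoscaled": {
                        k: float(v) for k, v in res.params.items()
                    },
                },
            )
            cv = res.loocv()
            pd.DataFrame(
                {
                    "sample_id": norm.sample_ids,
                    "observed": y,
                    "loocv_predicted": cv.per_sample_predictions,
                }
            ).to_csv(outdir / f"{name}_predictions.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        _log(stage, t0,
             liver_rmsecv=round(arms["liver"]["results"].rmsecv, 3),
             serum_rmsecv=round(arms["serum"]["results"].rmsecv, 3))

        stage = "rfe"
        t0 = time.perf_counter()
        subsets = {}
        for name in ("liver", "serum"):
            trace = rfe(arms[name]["X"], arms[name]["y"])
            arms[name]["trace"] = trace
            trace.to_frame().to_csv(outdir / f"{name}_rfe_trace.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            size = min(config.target_subset_size, len(retained))
            subsets[name] = optimal_subset(trace, target_size=size)
            (outdir / f"{name}_subset.txt").write_text("\n".join(subsets[name]) + "\n")
        _log(stage, t0)

        stage = "intersect"
        t0 = time.perf_counter()
        panel = intersect_panels(subsets["liver"], subsets["serum"])
        (outdir / "panel.txt").write_text("\n".join(panel) + "\n")
        _log(stage, t0, panel=len(panel))

        stage = "rank"
        t0 = time.perf_counter()
        records = build_records(panel, liver_corr, serum_corr, liver_norm, serum_norm, annotation)
        ranked = rank_panel(records, rules)
        panel_to_frame(ranked).to_csv(outdir / "ranked_panel.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        _log(stage, t0)

        stage = "combinations"
        t0 = time.perf_counter()
        sizes = [s for s in config.subset_sizes if s <= len(panel)]
        combos = []
        if sizes and len(panel) >= 2:
            combos = exhaustive_search(arms["serum"]["X"], arms["serum"]["y"], panel, sizes)
            combinations_to_frame(combos).to_csv(
                outdir / "combinations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
        _log(stage, t0, models=len(combos))

        stage = "manifest"
        outputs = sorted(
            p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        config_dict = config.to_dict()
        config_dict.pop("outdir")  # path is environment, not part of the result
        manifest = {
            "config": config_dict,
            "seed": config.seed,
            "stage_seeds": seeds,
            "outputs": {name: _sha256(outdir / name) for name in outputs},
        }
        _write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle.update(
        {
            "cohort": cohort,
            "retained": retained,
            "liver_norm": liver_norm,
            "serum_norm": serum_norm,
            "liver_corr": liver_corr,
            "serum_corr": serum_corr,
            "pca": pca,
            "arms": {
                name: {k: v for k, v in arm.items() if k != "X"} for name, arm in arms.items()
            },
            "subsets": subsets,
            "panel": panel,
            "ranked": ranked,
            "combinations": combos,
            "manifest": manifest,
        }
    )
    return bundle
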