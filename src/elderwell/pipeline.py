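"""End-to-end orchestration: load or synthesize -> score -> recode ->
describe -> MCA -> trees -> regressions, under one configuration, writing a
reproducible report bundle with a manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codebook import Codebook, default_codebook
from .descriptives import activity_distribution, frequency_counts, grouped_distribution, mwi_correlations
from .index import score_table
from .io import read_survey, write_table
from .mca import MCA, factor_table
from .recode import collapse_levels
from .regression import fit_all_outcomes, table3_layout, tidy_results
from .simulate import GeneratorConfig, generate_survey
from .tree import CARTRegressor

log = logging.getLogger("elderwell")

ALL_STAGES = ("score", "recode", "describe", "mca", "tree", "regress")

TREE_PREDICTORS = (
    "learn_elderly", "class_total", "places_total", "disability", "mobility",
    "health_good", "family_good", "friends_good", "working", "female",
    "married", "education_band", "no_children",
)

DESCRIBE_FIELDS = (
    "marital", "no_children", "education", "work", "health",
    "family_rel", "friends_rel", "learn_elderly",
)


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus per-stage knobs."""

    input_csv: str | None = None
    synthetic: GeneratorConfig | None = None
    codebook_path: str | None = None
    out_dir: str = "wellbeing_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    min_node: int = 20
    min_gain_frac: float = 0.01
    hc_variant: str = "HC1"
    missing_policy: str = "strict"
    mca_components: int = 5

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv / synthetic must be set")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"},
                  stages=tuple(raw.get("stages", ALL_STAGES)))
        if synth is not None:
            cfg.synthetic = GeneratorConfig(**synth)
        return cfg


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the configured stages, writing the bundle under ``out_dir``.

    Returns the manifest (also persisted as ``manifest.json``).  Any stage
    failure aborts with the stage name recorded in the partial manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    book = (
        Codebook.from_yaml(config.codebook_path)
        if config.codebook_path
        else default_codebook()
    )
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "min_node": config.min_node,
            "min_gain_frac": config.min_gain_frac,
            "hc_variant": config.hc_variant,
            "missing_policy": config.missing_policy,
            "mca_components": config.mca_components,
        },
        "row_counts": {},
        "completed": [],
    }

    def persist_manifest() -> None:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "load"
    try:
        if config.input_csv:
            table = read_survey(config.input_csv, book)
            manifest["input"] = {"kind": "csv", "path": str(config.input_csv)}
        else:
            gen = config.synthetic
            gen.seed = gen.seed or config.seed
            table, _ = generate_survey(gen, book)
            write_table(table, out / "synthetic_survey.csv")
            manifest["input"] = {"kind": "synthetic", "n": gen.n, "seed": gen.seed}
        manifest["row_counts"]["input"] = len(table)
        log.info("loaded %d respondents", len(table))

        scores = coded = None
        if "score" in config.stages:
            stage = "score"
            scores = score_table(table, book, policy=config.missing_policy)
            scored = pd.concat([table[["respondent_id"]], scores], axis=1)
            write_table(scored, out / "scored.csv")
            manifest["row_counts"]["scored"] = int(scores.notna().all(axis=1).sum())
            manifest["completed"].append(stage)

        if "recode" in config.stages and scores is not None:
            stage = "recode"
            coded = collapse_levels(table, scores)
            write_table(coded, out / "coded.csv")
            manifest["row_counts"]["coded"] = len(coded)
            manifest["completed"].append(stage)

        if "describe" in config.stages:
            stage = "describe"
            freq = pd.concat(
                [frequency_counts(table, f).to_frame() for f in DESCRIBE_FIELDS],
                ignore_index=True,
            )
            write_table(freq, out / "frequencies.csv")
            acts = activity_distribution(table)
            acts.index.name = "family"
            write_table(acts.reset_index(), out / "activities.csv")
            if scores is not None:
                corr = mwi_correlations(scores)
                corr.index.name = "score"
                write_table(corr.reset_index(), out / "mwi_correlations.csv")
                write_table(
                    grouped_distribution(scores, table["learn_elderly"]),
                    out / "wellbeing_by_attitude.csv",
                )
            manifest["completed"].append(stage)

        if "mca" in config.stages and coded is not None:
            stage = "mca"
            mca = MCA(n_components=config.mca_components).fit(coded)
            inert = pd.DataFrame(
                {
                    "dimension": range(1, len(mca.eigenvalues_) + 1),
                    "inertia": mca.eigenvalues_,
                    "explained_raw": mca.explained_inertia_[: len(mca.eigenvalues_)],
                    "explained_adjusted": mca.adjusted_inertia_[: len(mca.eigenvalues_)],
                }
            )
            write_table(inert, out / "mca_inertia.csv")
            cc = mca.column_coordinates_.copy()
            cc.index.name = "category"
            write_table(cc.reset_index(), out / "mca_category_coordinates.csv")
            rc = mca.row_coordinates_.copy()
            rc.index.name = "respondent_id"
            write_table(rc.reset_index(), out / "mca_individual_coordinates.csv")
            labels = coded.set_index("respondent_id")["learn_elderly"]
            write_table(
                factor_table(mca.result_, (1, 2), learn_labels=labels),
                out / "mca_factor_map.csv",
            )
            manifest["row_counts"]["mca_complete_cases"] = len(rc)
            manifest["completed"].append(stage)

        if "tree" in config.stages and coded is not None and scores is not None:
            stage = "tree"
            trees = {}
            for col, name in (
                ("MWI_Quality", "quality"),
                ("MWI_Satisfaction", "satisfaction"),
                ("MWI_Psychological", "psychological"),
            ):
                X = coded[list(TREE_PREDICTORS)]
                est = CARTRegressor(config.min_node, config.min_gain_frac).fit(X, scores[col])
                (out / f"tree_{name}.txt").write_text(est.render() + "\n", encoding="utf-8")
                (out / f"tree_{name}.json").write_text(est.to_json(indent=2), encoding="utf-8")
                trees[name] = est
                manifest["row_counts"][f"tree_{name}"] = est.tree_.n
            manifest["completed"].append(stage)

        if "regress" in config.stages and coded is not None and scores is not None:
            stage = "regress"
            results = fit_all_outcomes(
                coded, scores, variant=config.hc_variant
            )
            (out / "regression_table.txt").write_text(
                table3_layout(results) + "\n", encoding="utf-8"
            )
            write_table(tidy_results(results), out / "regression_tidy.csv")
            manifest["row_counts"]["regression"] = results[0].nobs
            manifest["completed"].append(stage)

    except Exception:
        manifest["failed_stage"] = stage
        persist_manifest()
        raise

    persist_manifest()
    return manifest
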