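"""Trial-table IO, pipeline configuration, and the end-to-end analysis.

The pipeline mirrors the analysis order of a control-group RTM study:

1. simulate (or load) the two-group trial table;
2. preprocess (center, compute changes, bin deviations);
3. mixed ANOVA on uncorrected changes (Deviation x Group);
4. fit the random-slope RTM model on the control group;
5. correct both groups' changes with the fitted average slope;
6. per-group ANOVAs on corrected changes (experimental: residual
   conformity effect; control: self-falsification check);
7. conformity scores per participant and score-level tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import correct_rating_changes
from .paradigm import DEFAULT_SCALE, RatingScale
from .preprocessing import preprocess
from .rtm_model import fit_control_hlm
from .scoring import score_participants
from .stats import (
    cell_means_table,
    holm_pairwise,
    one_sample_t,
    paired_t,
    pearson_between_participants,
    rm_anova_mixed,
    two_sample_t,
)
from .synthetic import GeneratorConfig, generate_experiment

__all__ = ["PipelineConfig", "read_trials", "write_trials", "run_pipeline"]

log = logging.getLogger("rtmconform")

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "item_id",
    "rating_1",
    "drawn_deviation",
    "presented_deviation",
    "rating_2",
]


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly.

    Round-trips losslessly through YAML (``to_yaml``/``from_yaml``).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_csv: str | None = None  # when set, load instead of simulate
    out_dir: str | None = None
    sphericity_alpha: float = 0.05
    reml: bool = True

    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        gen["scale"] = [self.generator.scale.minimum, self.generator.scale.maximum]
        return {
            "generator": gen,
            "input_csv": self.input_csv,
            "out_dir": self.out_dir,
            "sphericity_alpha": self.sphericity_alpha,
            "reml": self.reml,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = dict(d.get("generator", {}))
        if "scale" in gen:
            gen["scale"] = RatingScale(*gen["scale"])
        return cls(
            generator=GeneratorConfig(**gen),
            input_csv=d.get("input_csv"),
            out_dir=d.get("out_dir"),
            sphericity_alpha=d.get("sphericity_alpha", 0.05),
            reml=d.get("reml", True),
        )

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path, scale: RatingScale = DEFAULT_SCALE, discrete: bool = True) -> pd.DataFrame:
    """Load and validate a trial table CSV.

    Checks the documented header, rating bounds (discrete tables only),
    deviation range, and (participant, item) key uniqueness; errors name
    the first offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if discrete:
        for col in ("rating_1", "rating_2"):
            bad = df.index[(df[col] < scale.minimum) | (df[col] > scale.maximum)]
            if len(bad):
                raise ValueError(
                    f"row {bad[0]}: {col}={df.loc[bad[0], col]} outside "
                    f"[{scale.minimum}, {scale.maximum}]"
                )
    for col in ("drawn_deviation", "presented_deviation"):
        bad = df.index[~df[col].isin([-2, -1, 0, 1, 2])]
        if len(bad):
            raise ValueError(f"row {bad[0]}: {col}={df.loc[bad[0], col]} outside -2..+2")
    dup = df.duplicated(["participant_id", "item_id"])
    if dup.any():
        first = df.index[dup][0]
        raise ValueError(
            f"row {first}: duplicate (participant, item) = "
            f"({df.loc[first, 'participant_id']}, {df.loc[first, 'item_id']})"
        )
    bad_group = df.index[~df["group"].isin(["experimental", "control"])]
    if len(bad_group):
        raise ValueError(f"row {bad_group[0]}: unknown group label")
    return df


def _score_tests(scores: pd.DataFrame) -> dict:
    ok = scores.dropna(subset=["z_raw", "z_corrected"])
    if len(ok) < len(scores):
        warnings.warn(f"excluding {len(scores) - len(ok)} undefined scores")
    return {
        "n": int(len(ok)),
        "mean_z_raw": float(ok["z_raw"].mean()),
        "mean_z_corrected": float(ok["z_corrected"].mean()),
        "raw_vs_zero": one_sample_t(ok["z_raw"]).to_dict(),
        "corrected_vs_zero": one_sample_t(ok["z_corrected"]).to_dict(),
        "raw_vs_corrected": paired_t(ok["z_raw"], ok["z_corrected"]).to_dict(),
        "raw_corrected_correlation": pearson_between_participants(
            ok["z_raw"], ok["z_corrected"]
        ),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the results bundle and, when
    ``config.out_dir`` is set, writes all tables and a JSON summary."""
    stage = "load"
    try:
        if config.input_csv is not None:
            trials = read_trials(config.input_csv, config.generator.scale,
                                 discrete=config.generator.discretize)
        else:
            stage = "simulate"
            trials = generate_experiment(config.generator)
        if not (trials["group"] == "control").any():
            raise ValueError("control group absent: the RTM correction "
                             "requires a control-group fit")

        stage = "preprocess"
        items = preprocess(trials)

        stage = "group_comparison"
        by_part = items.groupby(["participant_id", "group"])["rating_1"].mean().reset_index()
        grp_t = two_sample_t(
            by_part.loc[by_part.group == "experimental", "rating_1"],
            by_part.loc[by_part.group == "control", "rating_1"],
        )

        stage = "mixed_anova"
        cells = cell_means_table(items, "c")
        groups = items.drop_duplicates("participant_id").set_index("participant_id")["group"]
        mixed = rm_anova_mixed(cells, groups, config.sphericity_alpha)
        per_group_raw = {
            g: rm_anova_mixed(
                cell_means_table(items[items.group == g], "c"),
                sphericity_alpha=config.sphericity_alpha,
            )
            for g in ("experimental", "control")
        }

        stage = "control_fit"
        fit = fit_control_hlm(items[items.group == "control"], reml=config.reml)
        log.info("control RTM fit:\n%s", fit.summary())

        stage = "correct"
        corrected = correct_rating_changes(items, fit.gamma10)

        stage = "corrected_anova"
        per_group_corrected = {}
        holm = {}
        for g in ("experimental", "control"):
            cm = cell_means_table(corrected[corrected.group == g], "s_hat")
            per_group_corrected[g] = rm_anova_mixed(
                cm, sphericity_alpha=config.sphericity_alpha
            )
            holm[g] = holm_pairwise(cm)

        stage = "score"
        scores = {
            g: score_participants(corrected[corrected.group == g])
            for g in ("experimental", "control")
        }
        score_tests = {g: _score_tests(s) for g, s in scores.items()}

        summary = {
            "package_version": __version__,
            "seed": config.generator.seed,
            "n_trials": int(len(trials)),
            "initial_rating_group_t": grp_t.to_dict(),
            "anova_uncorrected_mixed": mixed.to_dict(),
            "anova_uncorrected_per_group": {
                g: a.to_dict() for g, a in per_group_raw.items()
            },
            "control_rtm_fit": fit.to_dict(),
            "anova_corrected_per_group": {
                g: a.to_dict() for g, a in per_group_corrected.items()
            },
            "holm_pairwise_corrected": {
                g: h.to_dict(orient="records") for g, h in holm.items()
            },
            "score_tests": score_tests,
        }
        bundle = {
            "trials": trials,
            "items": corrected,
            "fit": fit,
            "scores": scores,
            "summary": summary,
        }

        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_trials(trials, out / "trials.csv")
            corrected.to_csv(out / "items.csv", index=False)
            for g, s in scores.items():
                s.to_csv(out / f"scores_{g}.csv", index=False)
            (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
            config.to_yaml(out / "config.yaml")
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
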