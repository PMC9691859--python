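"""End-to-end pipeline: records -> grouping -> smoothing -> clustering ->
cause-mix relative risks -> hazard contrast, from a single config.

Every stage output (TSV tables, PNG figures, JSON summary, run log) is
written into one output directory; all randomness derives from the config
seed through fixed offsets, so a rerun with the same config reproduces every
numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .causemix import ADJUST_AXES_DEFAULT, CauseShiftModel
from .cohort import EraDesign, apply_exclusions
from .hazard import HazardContrast
from .pattern import DeathPatternModel
from .records import read_records, write_records
from .simulate import CohortConfig, generate_cohort
from .taxonomy import default_taxonomy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

# fixed seed offsets so stages draw independent, reproducible streams
_SEED_CLUSTER = 101
_SEED_EMBED = 202


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration.  Exactly one of ``input_path`` /
    ``synthetic`` must be set."""

    output_dir: str
    input_path: str | None = None
    synthetic: CohortConfig | None = None
    era: EraDesign = field(default_factory=EraDesign)
    cluster_k: int = 2
    cluster_restarts: int = 10
    cluster_standardize: bool = True
    cluster_on_embedding: bool = False
    cluster_month_max: int = 36
    min_dot_size: int = 20
    adjust_axes: tuple[str, ...] = ADJUST_AXES_DEFAULT
    lowess_frac: float = 0.3
    lowess_robust_iters: int = 1
    wilcoxon_on_smoothed: bool = False
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("year_range", "transition_years"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = CohortConfig(**syn)
        if "era" in kwargs:
            era = dict(kwargs["era"])
            for key in ("pre_years", "immuno_years"):
                if key in era:
                    era[key] = tuple(era[key])
            if "excluded_years" in era:
                era["excluded_years"] = frozenset(era["excluded_years"])
            kwargs["era"] = EraDesign(**era)
        if "adjust_axes" in kwargs:
            kwargs["adjust_axes"] = tuple(kwargs["adjust_axes"])
        return cls(**kwargs)

    def describe(self) -> dict:
        out = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = out["synthetic"]
            syn["taxonomy"] = list(self.synthetic.taxonomy.categories)
            syn["cause_mix_pre"] = dict(self.synthetic.cause_mix_pre)
            syn["cause_mix_post"] = dict(self.synthetic.cause_mix_post)
        out["era"]["excluded_years"] = sorted(self.era.excluded_years)
        return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write the artifact bundle, return the JSON summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("codshift")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "python": sys.version.split()[0], "config": config.describe()}
    taxonomy = default_taxonomy()
    try:
        try:
            stage = "input"
            if config.synthetic is not None:
                records = generate_cohort(config.synthetic)
                taxonomy = config.synthetic.taxonomy
                write_records(records, out / "records.csv")
            else:
                records = read_records(config.input_path, taxonomy)
            summary["n_records"] = len(records)

            stage = "exclusions"
            retained, unknown = apply_exclusions(records, taxonomy)
            summary["n_unknown_cause_excluded"] = len(unknown)

            stage = "clustering"
            pattern_model = DeathPatternModel(
                retained, taxonomy, month_max=config.cluster_month_max, min_dot_size=config.min_dot_size
            )
            pattern_model.cube.write_tsv(out / "count_cube.tsv")
            pattern_model.features.write_tsv(out / "features.tsv")
            pat = pattern_model.fit(
                k=config.cluster_k,
                seed=config.seed + _SEED_CLUSTER,
                n_restarts=config.cluster_restarts,
                standardize=config.cluster_standardize,
                cluster_on_embedding=config.cluster_on_embedding,
            )
            clusters_df = pat.to_frame(with_embedding=config.make_figures, seed=config.seed + _SEED_EMBED)
            clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False, lineterminator="\n")
            summary["clustering"] = {
                "n_dots": int(len(pat.labels)),
                "within_ss": pat.clusters.inertia,
                "year_pattern": {
                    str(y): {
                        "cluster": int(r["cluster"]),
                        "majority_fraction": float(r["majority_fraction"]),
                        "ambiguous": bool(r["ambiguous"]),
                    }
                    for y, r in pat.year_pattern.iterrows()
                },
            }
            if config.make_figures:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                ax = pat.plot_embedding(seed=config.seed + _SEED_EMBED)
                ax.figure.savefig(out / "embedding.png", dpi=150)
                plt.close(ax.figure)

            stage = "cause_mix"
            shift_model = CauseShiftModel(records, taxonomy, config.era)
            shift = shift_model.fit(config.adjust_axes)
            shift.write_tsv(out / "cause_mix.tsv")
            summary["cause_mix"] = {
                "n_pre": len(shift_model.pre),
                "n_immuno": len(shift_model.immuno),
                "table": json.loads(shift.table.reset_index().to_json(orient="records")),
            }

            stage = "hazard"
            hazard = HazardContrast(
                shift_model.pre, shift_model.immuno, taxonomy, M=config.era.followup_cutoff_months
            ).fit(
                frac=config.lowess_frac,
                robust_iters=config.lowess_robust_iters,
                wilcoxon_on_smoothed=config.wilcoxon_on_smoothed,
            )
            hazard.write_tsv(out)
            summary["hazard"] = json.loads(hazard.table.reset_index().to_json(orient="records"))
            if config.make_figures:
                import matplotlib.pyplot as plt

                for name in hazard.curves:
                    ax = hazard.plot(name)
                    tag = name.replace("/", "_").replace(" ", "_")
                    ax.figure.savefig(out / f"hazard_{tag}.png", dpi=150)
                    plt.close(ax.figure)

            stage = "summary"
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            logger.info("pipeline complete: %s", out)
            return summary
        except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
            logger.exception("stage %s failed", stage)
            raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
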