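"""End-to-end orchestration: featurize -> classify -> regress.

A :class:`PipelineConfig` (typically loaded from YAML) names the input
corpus tables, the subsampling policy, the classification pairs and the
regression setup. :func:`run_pipeline` validates the config up front,
executes the stages, and writes every artifact together with a manifest
carrying the config hash and all seeds, so a rerun with the identical
config reproduces all deterministic outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import classification as cls
from . import corpus_io, regression
from .features import feature_table


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage is named in the message."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    inputs: list[dict]  # each: {path, corpus_label?}
    output_dir: Path
    subsample_n: int | None = None
    subsample_seed: int = 0
    subsample_order: str = "after_filtering"  # or "before_filtering"
    classification_pairs: list[tuple[str, str]] = field(default_factory=list)
    classifier_family: str = "knn"
    k_grid: Sequence[int] = cls.DEFAULT_K_GRID
    n_architectures: int = 100
    split_seed: int = 0
    classifier_seed: int = 0
    metadata_path: Path | None = None
    regression_response: str = "entropy_rate"
    regression_base_terms: Sequence[str] = ("volume", "max_date", "object_type")
    regression_alternative_terms: Sequence[str] = ("site", "preservation", "material")
    regression_interaction_terms: Sequence[str] = (
        "volume*preservation",
        "volume*object_type",
        "max_date*object_type",
    )
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls_, d: Mapping[str, Any]) -> "PipelineConfig":
        sub = d.get("subsample", {}) or {}
        clf = d.get("classification", {}) or {}
        reg = d.get("regression", {}) or {}
        cfg = cls_(
            inputs=list(d["inputs"]),
            output_dir=Path(d["output_dir"]),
            subsample_n=sub.get("n"),
            subsample_seed=int(sub.get("seed", 0)),
            subsample_order=sub.get("order", "after_filtering"),
            classification_pairs=[tuple(p) for p in clf.get("pairs", [])],
            classifier_family=clf.get("family", "knn"),
            k_grid=tuple(clf.get("k_grid", cls.DEFAULT_K_GRID)),
            n_architectures=int(clf.get("n_architectures", 100)),
            split_seed=int(clf.get("split_seed", 0)),
            classifier_seed=int(clf.get("seed", 0)),
            metadata_path=Path(reg["metadata"]) if reg.get("metadata") else None,
            regression_response=reg.get("response", "entropy_rate"),
            regression_base_terms=tuple(
                reg.get("base_terms", ("volume", "max_date", "object_type"))
            ),
            regression_alternative_terms=tuple(
                reg.get("alternative_terms", ("site", "preservation", "material"))
            ),
            regression_interaction_terms=tuple(
                reg.get(
                    "interaction_terms",
                    ("volume*preservation", "volume*object_type", "max_date*object_type"),
                )
            ),
            raw=dict(d),
        )
        if cfg.subsample_order not in ("after_filtering", "before_filtering"):
            raise ValueError(f"unknown subsample order {cfg.subsample_order!r}")
        return cfg

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls_.from_dict(yaml.safe_load(fh))

    def validate_paths(self) -> None:
        missing = [
            str(item["path"]) for item in self.inputs if not Path(item["path"]).exists()
        ]
        if self.metadata_path is not None and not self.metadata_path.exists():
            missing.append(str(self.metadata_path))
        if missing:
            raise PipelineError(f"stage 'validate': missing input path(s): {missing}")

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Everything a pipeline run produced."""

    config: PipelineConfig
    features: pd.DataFrame
    preprocessing: dict[str, dict]
    classification: dict[str, dict] = field(default_factory=dict)
    regression_ladder: pd.DataFrame | None = None
    regression_best: regression.ModelFit | None = None
    diagnostics: regression.DiagnosticsReport | None = None
    manifest: dict = field(default_factory=dict)


def _featurize(config: PipelineConfig) -> tuple[pd.DataFrame, dict[str, dict]]:
    all_seqs = []
    reports: dict[str, dict] = {}
    for item in config.inputs:
        records = corpus_io.read_sequence_table(item["path"])
        if "corpus_label" in item:
            records = [
                corpus_io.RawRecord(r.source_id, item["corpus_label"], r.dialect, r.raw)
                for r in records
            ]
        if config.subsample_order == "before_filtering" and config.subsample_n:
            idx = corpus_io.subsample_corpus(
                list(range(len(records))), config.subsample_n, config.subsample_seed
            )
            records = [records[i] for i in idx]
        seqs, report = corpus_io.clean_corpus(records)
        if config.subsample_order == "after_filtering" and config.subsample_n:
            seqs = corpus_io.subsample_corpus(seqs, config.subsample_n, config.subsample_seed)
        label = seqs[0].corpus_label if seqs else item.get("corpus_label", item["path"])
        reports[str(label)] = {
            "n_input": report.n_input,
            "n_kept": report.n_kept,
            "n_empty": report.n_empty,
            "n_used": len(seqs),
        }
        all_seqs.extend(seqs)
    return feature_table(all_seqs), reports


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute featurize -> classify (per pair) -> regress and write artifacts."""
    config.validate_paths()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    try:
        features, reports = _featurize(config)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(f"stage 'featurize' failed: {exc}") from exc
    bundle = ReportBundle(config=config, features=features, preprocessing=reports)
    features.to_csv(out / "features.csv", index=False)

    for pair in config.classification_pairs:
        key = f"{pair[0]}_vs_{pair[1]}"
        try:
            points = features[features["corpus_label"].isin(pair)]
            split = cls.standardize_and_split(points, cls.SplitSpec(seed=config.split_seed))
            if config.classifier_family == "mlp":
                runs = cls.mlp_classify(
                    split,
                    n_architectures=config.n_architectures,
                    seed=config.classifier_seed,
                )
            else:
                runs = cls.knn_sweep(split, config.k_grid)
            cls.runs_table(runs).to_csv(out / f"runs_{key}.csv", index=False)
            bundle.classification[key] = cls.summarize_runs(runs)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'classify:{key}' failed: {exc}") from exc

    if config.metadata_path is not None:
        try:
            meta = pd.read_csv(config.metadata_path)
            resp = config.regression_response
            joined = meta.merge(
                features[["source_id", "h"]].rename(columns={"h": resp}),
                on="source_id",
                how="inner",
            ) if resp not in meta.columns else meta
            ladder, best = regression.stepwise_aic_selection(
                joined,
                base_terms=config.regression_base_terms,
                alternative_terms=config.regression_alternative_terms,
                interaction_terms=config.regression_interaction_terms,
                response=resp,
            )
            bundle.regression_ladder = regression.ladder_table(ladder)
            bundle.regression_best = best
            bundle.diagnostics = regression.model_diagnostics(best)
            bundle.regression_ladder.to_csv(out / "model_ladder.csv", index=False)
            best.coefficients.to_csv(out / "best_model_coefficients.csv")
            with open(out / "diagnostics.json", "w") as fh:
                json.dump(
                    {
                        "shapiro_p": bundle.diagnostics.shapiro_p,
                        "bp_p": bundle.diagnostics.bp_p,
                        "flags": bundle.diagnostics.flags(),
                    },
                    fh,
                    indent=2,
                )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'regress' failed: {exc}") from exc

    bundle.manifest = {
        "config_hash": config.config_hash(),
        "seeds": {
            "subsample": config.subsample_seed,
            "split": config.split_seed,
            "classifier": config.classifier_seed,
        },
        "config": config.raw,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "preprocessing": bundle.preprocessing,
                "classification": bundle.classification,
                "regression_best": bundle.regression_best.label
                if bundle.regression_best
                else None,
            },
            fh,
            indent=2,
        )
    (out / "report.md").write_text(export_report(bundle))
    return bundle


def export_report(bundle: ReportBundle) -> str:
    """Render a human-readable Markdown summary of a pipeline run."""
    lines = ["# signseq pipeline report", ""]
    lines.append(f"Config hash: `{bundle.manifest.get('config_hash', 'n/a')}`")
    lines.append("")
    lines.append("## Corpora")
    for label, grp in bundle.features.groupby("corpus_label"):
        lines.append(
            f"- **{label}**: {len(grp)} sequences; median length "
            f"{grp['n_tokens'].median():.0f} tokens; median H "
            f"{grp['H'].median():.2f}, h {grp['h'].median():.2f}, "
            f"TTR {grp['TTR'].median():.2f}, r {grp['r'].median():.2f}"
        )
    lines.append("")
    lines.append("## Classification")
    if bundle.classification:
        for key, summary in bundle.classification.items():
            lines.append(
                f"- **{key}**: {summary.get('n_converged', 0)} runs; "
                f"mean accuracy {summary.get('accuracy_mean', float('nan')):.3f} "
                f"(NIR {summary.get('nir', float('nan')):.3f}); "
                f"{summary.get('pct_significant', 0.0):.0f}% significant after Bonferroni"
            )
    else:
        lines.append("_not run_")
    lines.append("")
    lines.append("## Regression")
    if bundle.regression_best is not None:
        b = bundle.regression_best
        lines.append(
            f"Best model by AIC: `{b.label}` "
            f"(AIC {b.aic:.1f}, F {b.f_stat:.2f}, R^2 {b.r_squared:.3f})"
        )
        if bundle.diagnostics is not None:
            flags = bundle.diagnostics.flags()
            lines.append(f"Diagnostics flags: {flags if flags else 'none'}")
    else:
        lines.append("_not run_")
    lines.append("")
    return "\n".join(lines)
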