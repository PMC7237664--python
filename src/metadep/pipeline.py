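"""End-to-end orchestration: simulate → evaluate → cohort stats → markers.

A :class:`RunConfig` (YAML-serializable) drives the full pipeline on one
shared fold plan per outcome branch.  Every artifact is written under the
output directory as TSV/JSON, and a MANIFEST records each file with a
checksum, the config and the seed, so two runs with the same (config, seed)
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, apply_exclusions, binarize_outcome, generate_cohort
from .crossval import default_model_registry, make_fold_plan, run_nested_cv
from .io import read_cohort_tsv, write_cohort
from .markers import (
    adjusted_regression_stats,
    consistent_markers,
    pairwise_hsic_table,
    selection_frequency,
)
from .stats import build_cohort_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "orchestrate"]


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML unchanged."""

    seed: int = 0
    out_dir: str = "results"
    cohort_tsv: str | None = None  # read an existing cohort instead of simulating
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    models: list[str] = field(default_factory=list)  # empty = full registry
    outcome_kinds: list[str] = field(default_factory=lambda: ["quantitative", "binary"])
    cutoffs: list[int] = field(default_factory=lambda: [16, 19])
    k_grid: list[int] = field(default_factory=lambda: [5, 10, 15, 20, 30, 50])
    consistency_threshold: int = 4
    include_delegated: bool = False

    def __post_init__(self):
        for kind in self.outcome_kinds:
            if kind not in ("quantitative", "binary"):
                raise ValueError(f"unknown outcome kind {kind!r}")
        for c in self.cutoffs:
            if int(c) < 1:
                raise ValueError("cutoffs must be positive integers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_cohort(cfg: RunConfig) -> Cohort:
    if cfg.cohort_tsv:
        cohort = read_cohort_tsv(cfg.cohort_tsv)
    else:
        overrides = dict(cfg.cohort)
        overrides.setdefault("seed", cfg.seed)
        cohort = generate_cohort(CohortConfig(**overrides))
    return apply_exclusions(cohort)


def orchestrate(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Any stage failure leaves partial outputs in place with the MANIFEST
    noting the failure point, then re-raises.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "files": {},
        "status": "running",
        "failed_stage": None,
    }

    def record(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def flush():
        mpath = out / "MANIFEST.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        cohort = _resolve_cohort(cfg)
        for p in write_cohort(cohort, out / "cohort"):
            record(p)

        stage = "evaluate"
        registry_names = cfg.models or None
        results = {}
        rows = []
        for kind in cfg.outcome_kinds:
            cutoffs = cfg.cutoffs if kind == "binary" else [None]
            for cutoff in cutoffs:
                registry = default_model_registry(
                    kind, k_grid=cfg.k_grid, include_delegated=cfg.include_delegated
                )
                names = registry_names or list(registry)
                labels = (
                    binarize_outcome(cohort.outcome_scores, cutoff)
                    if kind == "binary"
                    else None
                )
                plan = make_fold_plan(cohort.n, cfg.seed, stratify_labels=labels)
                branch = kind if cutoff is None else f"{kind}_{cutoff}"
                branch_results = {}
                for requested in names:
                    # kr and svm specs are branch twins; translate across kinds
                    name = requested
                    if name not in registry:
                        swapped = (
                            requested.replace("svm", "kr")
                            if "svm" in requested
                            else requested.replace("kr", "svm")
                        )
                        if swapped in registry:
                            name = swapped
                        else:
                            raise ValueError(
                                f"unknown model {requested!r} for {kind}"
                            )
                    if name in branch_results:
                        continue
                    res = run_nested_cv(
                        cohort,
                        registry[name],
                        plan,
                        outcome_kind=kind,
                        cutoff=cutoff or 16,
                    )
                    branch_results[name] = res
                    for i, s in enumerate(res.scores):
                        rows.append(
                            {
                                "branch": branch,
                                "model": name,
                                "fold": i,
                                "score": s,
                            }
                        )
                results[branch] = branch_results
        scores_path = out / "scores.tsv"
        pd.DataFrame(rows).to_csv(scores_path, sep="\t", index=False)
        record(scores_path)
        prov_path = out / "evaluation.json"
        prov_path.write_text(
            json.dumps(
                {
                    b: {m: r.to_dict() for m, r in br.items()}
                    for b, br in results.items()
                },
                indent=2,
            )
        )
        record(prov_path)

        stage = "cohort_stats"
        for cutoff in cfg.cutoffs:
            rep = build_cohort_report(cohort, cutoff=cutoff)
            p = out / f"cohort_report_cutoff{cutoff}.tsv"
            rep.to_csv(p, sep="\t", index=False)
            record(p)

        stage = "markers"
        marker_files = _marker_stage(cfg, cohort, results, out)
        for p in marker_files:
            record(p)

        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        flush()
        raise
    flush()
    return out


def _marker_stage(cfg: RunConfig, cohort: Cohort, results: dict, out: Path) -> list[Path]:
    """Selection frequencies, consistency, adjusted stats, dependency table."""
    written = []
    freq_by_branch: dict[str, dict[str, pd.DataFrame]] = {}
    for branch, branch_results in results.items():
        freqs = {}
        for name, res in branch_results.items():
            if name.endswith(("_all", "_covariates")) or not any(res.selected_features):
                continue
            spec_selects = len(res.selected_features) == 5 and any(
                len(s) < len(cohort.features.columns) for s in res.selected_features
            )
            if spec_selects:
                freqs[name] = selection_frequency(res.selected_features)
        freq_by_branch[branch] = freqs
        if freqs:
            table = pd.concat(
                {name: f["count"] for name, f in freqs.items()}, axis=1
            ).fillna(0).astype(int)
            p = out / f"selection_frequency_{branch}.tsv"
            table.to_csv(p, sep="\t")
            written.append(p)

    # consistency requires one quantitative and one binary branch
    quant = freq_by_branch.get("quantitative", {})
    binary_branches = [b for b in freq_by_branch if b.startswith("binary")]
    markers: list[str] = []
    if quant and binary_branches:
        bfreqs = freq_by_branch[binary_branches[0]]

        def family(name: str) -> str:
            # kr and svm are the two faces of the same kernel-predictor family
            return (
                name.replace("_svm", "_K").replace("_kr", "_K")
                .replace("svm_", "K_").replace("kr_", "K_")
            )

        for model_q, fq in quant.items():
            match = next(
                (fb for name_b, fb in bfreqs.items() if family(name_b) == family(model_q)),
                None,
            )
            if match is None:
                continue
            markers.extend(
                m
                for m in consistent_markers(fq, match, cfg.consistency_threshold)
                if m not in cohort.covariate_names
            )
    markers = sorted(set(markers))

    cov_df = cohort.features[cohort.covariate_names]
    rows = []
    for m in markers:
        coef_q, p_q = adjusted_regression_stats(
            cohort.features[m].to_numpy(), cov_df, cohort.outcome_scores, "quantitative"
        )
        coef_b, p_b = adjusted_regression_stats(
            cohort.features[m].to_numpy(),
            cov_df,
            binarize_outcome(cohort.outcome_scores, cfg.cutoffs[0]),
            "binary",
        )
        rows.append(
            {
                "feature": m,
                "coef_quantitative": coef_q,
                "p_quantitative": p_q,
                "coef_binary": coef_b,
                "p_binary": p_b,
            }
        )
    p = out / "consistent_markers.tsv"
    pd.DataFrame(rows, columns=[
        "feature",
        "coef_quantitative",
        "p_quantitative",
        "coef_binary",
        "p_binary",
    ]).to_csv(p, sep="\t", index=False)
    written.append(p)

    dep_cols = ["outcome_score"] + list(cohort.covariate_names) + markers
    dep_df = cohort.features.reindex(columns=[c for c in dep_cols if c != "outcome_score"]).copy()
    dep_df.insert(0, "outcome_score", cohort.outcome_scores)
    kinds = dict(cohort.feature_kinds)
    kinds["outcome_score"] = "continuous"
    dep = pairwise_hsic_table(dep_df, kinds, covariate_names=cohort.covariate_names)
    p = out / "dependency_table.tsv"
    dep.to_csv(p, sep="\t")
    written.append(p)
    return written
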