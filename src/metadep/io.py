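"""Cohort readers and writers (TSV table + JSON sidecar)."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortConfig, EffectSpec, COVARIATE_KINDS
from .kernels import CATEGORICAL, CONTINUOUS

logger = logging.getLogger(__name__)

__all__ = ["write_cohort", "read_cohort_tsv", "CohortSchemaError"]

OUTCOME_COLUMN = "outcome_score"
_FLAG_COLUMNS = ("missing_flag", "unreliable_flag")


class CohortSchemaError(ValueError):
    """The cohort file does not match the declared schema."""


def write_cohort(cohort: Cohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``cohort.tsv`` (subject-ID first column) and ``cohort.json``.

    The sidecar records the generating config (when present), feature kinds,
    covariate names and ground-truth causal ids, which is everything needed
    to round-trip the cohort bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = cohort.features.copy()
    table.insert(0, "subject_id", np.arange(cohort.n))
    table[OUTCOME_COLUMN] = cohort.outcome_scores
    table["missing_flag"] = cohort.missing_flag.astype(int)
    table["unreliable_flag"] = cohort.unreliable_flag.astype(int)
    tsv_path = out_dir / "cohort.tsv"
    table.to_csv(tsv_path, sep="\t", index=False)

    cfg = None
    if cohort.config is not None:
        cfg = dataclasses.asdict(cohort.config)
        if cfg.get("effect_functions") is not None:
            cfg["effect_functions"] = [
                dataclasses.asdict(e) for e in cohort.config.effect_functions
            ]
    sidecar = {
        "config": cfg,
        "seed": None if cohort.config is None else cohort.config.seed,
        "feature_kinds": cohort.feature_kinds,
        "covariate_names": cohort.covariate_names,
        "causal_feature_ids": cohort.causal_feature_ids,
        "redundant_blocks": cohort.redundant_blocks,
    }
    json_path = out_dir / "cohort.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return tsv_path, json_path


def _config_from_dict(cfg: dict | None) -> CohortConfig | None:
    if cfg is None:
        return None
    if cfg.get("effect_functions") is not None:
        cfg = dict(cfg)
        cfg["effect_functions"] = tuple(
            EffectSpec(**e) for e in cfg["effect_functions"]
        )
    return CohortConfig(**cfg)


def read_cohort_tsv(path: str | Path, sidecar: str | Path | None = None) -> Cohort:
    """Read a cohort table; rows with a missing outcome are listwise-deleted.

    ``sidecar`` defaults to ``cohort.json`` next to the table.  Feature kinds
    come from the sidecar; covariates absent from it fall back to the
    standard eight-covariate schema.  Non-numeric metabolite cells raise a
    parse error naming the offending row and column.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_name("cohort.json")
    meta = json.loads(Path(sidecar).read_text()) if Path(sidecar).exists() else {}

    table = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in table.columns:
        raise CohortSchemaError("missing required column: subject_id")
    if OUTCOME_COLUMN not in table.columns:
        raise CohortSchemaError(f"missing required column: {OUTCOME_COLUMN}")

    feature_cols = [
        c
        for c in table.columns
        if c not in ("subject_id", OUTCOME_COLUMN, *_FLAG_COLUMNS)
    ]
    kinds = dict(meta.get("feature_kinds") or {})
    for c in feature_cols:
        kinds.setdefault(c, COVARIATE_KINDS.get(c, CONTINUOUS))
        if kinds[c] not in (CONTINUOUS, CATEGORICAL):
            raise CohortSchemaError(f"unknown kind {kinds[c]!r} for column {c}")
    kinds = {c: kinds[c] for c in feature_cols}
    covariate_names = list(
        meta.get("covariate_names")
        or [c for c in feature_cols if c in COVARIATE_KINDS]
    )

    numeric = pd.DataFrame(index=table.index)
    for c in feature_cols:
        converted = pd.to_numeric(table[c], errors="coerce")
        bad = converted.isna() & table[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CohortSchemaError(
                f"non-numeric value {table[c][row]!r} in column {c!r}, row {row}"
            )
        numeric[c] = converted

    outcome = pd.to_numeric(table[OUTCOME_COLUMN], errors="coerce")
    missing_outcome = outcome.isna()
    if missing_outcome.any():
        logger.info(
            "listwise deletion: %d rows with missing outcome",
            int(missing_outcome.sum()),
        )
    keep = ~missing_outcome
    numeric = numeric.loc[keep].reset_index(drop=True)
    n = len(numeric)

    def flag(col):
        if col in table.columns:
            return (
                pd.to_numeric(table[col], errors="coerce")
                .fillna(0)
                .loc[keep]
                .to_numpy()
                .astype(bool)
            )
        return np.zeros(n, dtype=bool)

    numeric.index = pd.RangeIndex(n, name="subject")
    cohort = Cohort(
        features=numeric,
        feature_kinds=kinds,
        covariate_names=covariate_names,
        outcome_scores=outcome.loc[keep].to_numpy(dtype=float).astype(int),
        missing_flag=flag("missing_flag"),
        unreliable_flag=flag("unreliable_flag"),
        causal_feature_ids=list(meta.get("causal_feature_ids") or []),
        redundant_blocks=[list(b) for b in (meta.get("redundant_blocks") or [])],
        config=_config_from_dict(meta.get("config")),
    )
    cohort.validate()
    return cohort
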