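"""End-to-end orchestration: cohort in, summary/agreement/ROC/grid-search out.

The full analysis mirrors the structure of a single-centre diagnostic
study: every patient has pathology; ultrasound and MRI depths are each
analysed against pathology on the subset where that modality was
measured; ROC analyses run per modality on its own available subset; the
composite us/mrDOI grid search runs on the complete-case subset only.
Every subset size and every skipped stage is logged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .agreement import AgreementReport, bland_altman
from .fusion import (
    DEFAULT_PERCENTILES,
    GridSearchResult,
    complete_cases,
    compose_doi,
    grid_search,
)
from .roc import CutoffCriterion, RocReport, roc_report
from .synthetic import (
    COHORT_COLUMNS,
    CohortSummary,
    GeneratorParams,
    PatientRecord,
    generate_cohort,
    summarize_cohort,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_full_analysis",
    "make_fixtures",
    "regime_change_params",
]

logger = logging.getLogger("doifusion")

REQUIRED_COLUMNS = ("patient_id", "p_doi_mm", "clnm")
_NUMERIC_COLUMNS = ("p_doi_mm", "us_doi_mm", "mr_doi_mm")


class AnalysisConfig(BaseModel):
    """Configuration of one full analysis run.

    Provide either ``input_csv`` (a cohort table on disk) or ``generator``
    (synthetic-cohort parameters); with neither, the default synthetic
    cohort is generated from ``seed``.
    """

    model_config = ConfigDict(frozen=True)

    input_csv: Optional[Path] = None
    generator: Optional[GeneratorParams] = None
    percentiles: Tuple[int, ...] = DEFAULT_PERCENTILES
    cutoff_criterion: CutoffCriterion = "youden"
    percentile_method: str = "linear"
    out_dir: Optional[Path] = None
    seed: int = 0
    verbosity: int = Field(default=0, ge=0, le=2)

    @model_validator(mode="after")
    def _check_percentiles(self) -> "AnalysisConfig":
        p = self.percentiles
        if any(not 1 <= v <= 99 for v in p):
            raise ValueError("percentile levels must lie within [1, 99]")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("percentile levels must be strictly increasing")
        if self.input_csv is not None and self.generator is not None:
            raise ValueError("provide input_csv or generator, not both")
        return self


@dataclass
class AnalysisReport:
    """All results of one run plus provenance (config, seed, version)."""

    summary: CohortSummary
    agreement: Dict[str, AgreementReport]  # keys: usDOI, mrDOI
    roc: Dict[str, RocReport]  # keys: usDOI, mrDOI, pDOI, composite
    grid: Optional[GridSearchResult]
    subset_sizes: Dict[str, int]
    skipped: List[str]
    provenance: dict

    def to_dict(self, include_timestamp: bool = True) -> dict:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("generated_at", None)
        return {
            "summary": self.summary.to_dict(),
            "agreement": {k: v.to_dict() for k, v in self.agreement.items()},
            "roc": {k: v.to_dict() for k, v in self.roc.items()},
            "grid_search": self.grid.to_dict() if self.grid is not None else None,
            "subset_sizes": self.subset_sizes,
            "skipped_stages": self.skipped,
            "provenance": prov,
        }

    def to_json(self, include_timestamp: bool = True, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(include_timestamp), **kwargs)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Empty cells become missing values.  Raises a schema error when a
    required column is absent and a row-level error (listing 1-based data
    row numbers) for malformed numerics, non-binary CLNM values, negative
    depths or unknown stage labels.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing required column(s) {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"].str.strip()
    row_errors: List[str] = []

    for col in _NUMERIC_COLUMNS:
        if col not in raw.columns:
            df[col] = np.nan
            continue
        cleaned = raw[col].str.strip().mask(lambda s: s == "")
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = cleaned.notna() & parsed.isna()
        for i in raw.index[bad]:
            row_errors.append(f"row {i + 1}: {col}={cleaned[i]!r} is not a number")
        df[col] = parsed

    clnm_raw = raw["clnm"].str.strip()
    clnm = pd.to_numeric(clnm_raw.mask(lambda s: s == ""), errors="coerce")
    bad = clnm.isna() | ~clnm.isin([0, 1])
    for i in raw.index[bad]:
        row_errors.append(f"row {i + 1}: clnm={clnm_raw[i]!r} is not 0/1")
    df["clnm"] = clnm

    for col in ("c_t", "c_n", "c_stage"):
        df[col] = (
            raw[col].str.strip().mask(lambda s: s == "") if col in raw.columns else np.nan
        )

    if row_errors:
        raise ValueError(f"{path.name}: invalid rows:\n  " + "\n  ".join(row_errors))
    df["clnm"] = df["clnm"].astype(int)

    # full per-record validation (positivity, finiteness, category levels)
    for i, row in df.iterrows():
        try:
            PatientRecord.from_row(row)
        except Exception as exc:  # pydantic ValidationError
            row_errors.append(f"row {i + 1}: {exc}")
    if row_errors:
        raise ValueError(f"{path.name}: invalid rows:\n  " + "\n  ".join(row_errors))
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    """Write a cohort table: UTF-8, LF endings, empty fields for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, na_rep="", lineterminator="\n", encoding="utf-8")
    return path


def _paired_subset(cohort: pd.DataFrame, col: str) -> pd.DataFrame:
    return cohort[cohort[col].notna() & cohort["p_doi_mm"].notna()]


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the whole pipeline on one cohort.

    Stages whose preconditions fail on the given cohort (for example a
    missing modality or a single-class subset) are skipped with a logged
    warning and recorded in ``report.skipped``; everything else runs.
    Deterministic for a fixed config and seed.
    """
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
        source = {"input_csv": str(config.input_csv)}
    else:
        params = config.generator or GeneratorParams(seed=config.seed)
        cohort = generate_cohort(params)
        source = {"generator": json.loads(params.model_dump_json())}

    skipped: List[str] = []
    agreement: Dict[str, AgreementReport] = {}
    roc: Dict[str, RocReport] = {}

    summary = summarize_cohort(cohort)

    subsets = {
        "n_total": len(cohort),
        "n_us": int(cohort["us_doi_mm"].notna().sum()),
        "n_mri": int(cohort["mr_doi_mm"].notna().sum()),
        "n_complete": len(complete_cases(cohort)),
    }
    logger.info("subset sizes: %s", subsets)

    for label, col in (("usDOI", "us_doi_mm"), ("mrDOI", "mr_doi_mm")):
        sub = _paired_subset(cohort, col)
        try:
            agreement[label] = bland_altman(sub[col], sub["p_doi_mm"])
        except ValueError as exc:
            skipped.append(f"agreement/{label}: {exc} (n={len(sub)})")
            logger.warning("skipping agreement for %s: %s", label, exc)

    for label, col in (("usDOI", "us_doi_mm"), ("mrDOI", "mr_doi_mm"), ("pDOI", "p_doi_mm")):
        sub = cohort[cohort[col].notna()]
        try:
            roc[label] = roc_report(
                sub[col].to_numpy(float),
                sub["clnm"].to_numpy(int),
                criterion=config.cutoff_criterion,
            )
        except ValueError as exc:
            skipped.append(f"roc/{label}: {exc} (n={len(sub)})")
            logger.warning("skipping ROC for %s: %s", label, exc)

    grid: Optional[GridSearchResult] = None
    try:
        grid = grid_search(
            cohort, config.percentiles, percentile_method=config.percentile_method
        )
        cc = complete_cases(cohort)
        composite = compose_doi(
            cc["us_doi_mm"].to_numpy(float),
            cc["mr_doi_mm"].to_numpy(float),
            grid.best_threshold,
        )
        roc["composite"] = roc_report(
            composite, cc["clnm"].to_numpy(int), criterion=config.cutoff_criterion
        )
    except ValueError as exc:
        skipped.append(f"grid_search: {exc}")
        logger.warning("skipping grid search: %s", exc)

    report = AnalysisReport(
        summary=summary,
        agreement=agreement,
        roc=roc,
        grid=grid,
        subset_sizes=subsets,
        skipped=skipped,
        provenance={
            "software": "doifusion",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(config.model_dump_json()),
            "source": source,
            "generated_at": datetime.now(timezone.utc).isoformat(),
        },
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        if grid is not None:
            grid.to_frame().to_csv(out / "grid_search.csv", index=False, lineterminator="\n")
        for label, rep in roc.items():
            pd.DataFrame(
                rep.curve, columns=["fpr", "tpr", "threshold"]
            ).to_csv(out / f"roc_{label}.csv", index=False, lineterminator="\n")
        logger.info("wrote report to %s", out)

    return report


def regime_change_params(seed: int = 0, n: int = 200) -> GeneratorParams:
    """Cohort parameters with a strong ultrasound regime change at 10 mm.

    Beyond the knot the deep slope of -1 flattens usDOI entirely (deep
    depths become uninformative on ultrasound), while MRI keeps tracking
    pathology; both modalities fully available.  Used for threshold-
    recovery studies of the grid search.
    """
    return GeneratorParams(
        n_patients=n,
        us_bias_shallow=0.88,
        us_bias_deep_slope=-1.0,
        us_knot_mm=10.0,
        us_sd=1.59,
        mr_bias=2.43,
        mr_sd=2.39,
        us_avail_beta0=50.0,
        us_avail_beta1=0.0,
        mr_avail_prob=1.0,
        seed=seed,
    )


#: Tiny hand-checkable cohort: depths and outcomes chosen so the pDOI AUC
#: can be enumerated over the 4x4 positive-negative pairs by hand (15/16).
TINY_COHORT_ROWS = [
    # patient_id, p_doi_mm, us_doi_mm, mr_doi_mm, clnm
    ("T001", 2.0, 2.5, 4.0, 0),
    ("T002", 3.0, 3.5, 5.5, 0),
    ("T003", 4.0, 4.5, 6.5, 0),
    ("T004", 6.0, 6.5, 8.5, 1),
    ("T005", 8.0, 8.5, 10.5, 0),
    ("T006", 10.0, 10.5, 12.5, 1),
    ("T007", 12.0, 11.0, 14.5, 1),
    ("T008", 15.0, 12.0, 17.5, 1),
]

TINY_COHORT_EXPECTED = {
    "pdoi_auc": 15 / 16,  # positives {6,10,12,15} vs negatives {2,3,4,8}
    "n_pos": 4,
    "n_neg": 4,
}


def _tiny_cohort() -> pd.DataFrame:
    df = pd.DataFrame(
        TINY_COHORT_ROWS, columns=["patient_id", "p_doi_mm", "us_doi_mm", "mr_doi_mm", "clnm"]
    )
    for col in ("c_t", "c_n", "c_stage"):
        df[col] = None
    return df[list(COHORT_COLUMNS)]


def make_fixtures(seed: int = 0, out_dir="fixtures") -> List[Path]:
    """Write the standard test cohorts to ``out_dir``.

    Produces the default study-calibrated cohort, the regime-change
    recovery cohort, the tiny hand-checkable cohort and its expected
    values.  Deterministic in ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        write_cohort_csv(
            generate_cohort(GeneratorParams(seed=seed)), out / "cohort_default.csv"
        ),
        write_cohort_csv(
            generate_cohort(regime_change_params(seed=seed)),
            out / "cohort_regime_change.csv",
        ),
        write_cohort_csv(_tiny_cohort(), out / "cohort_tiny.csv"),
    ]
    expected = out / "cohort_tiny_expected.json"
    expected.write_text(json.dumps(TINY_COHORT_EXPECTED, indent=2) + "\n", encoding="utf-8")
    paths.append(expected)
    return paths
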