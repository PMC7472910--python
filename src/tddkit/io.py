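"""File dialects, run configuration and the end-to-end pipeline.

Cohort tables mirror the patient-results layout of the study: one row per
patient with eight relative TDD scores (acute and 3-month, right/left hand
and foot), a free-text lesion annotation and a ``side_diff`` column holding
examiner side-difference flags as ``{timepoint}_{site}`` tokens separated by
semicolons.  Volumes are NIfTI-1 (optionally gzipped): integer labels for
parcellations, strictly 0/1 for lesion masks.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort_stats import paired_t
from .lesion_mapping import (LabelVolume, LesionMask, NodeCriteria,
                             build_matrix, node_symptom_test,
                             side_composite_scores,
                             split_into_contiguous_nodes,
                             target_area_association)
from .normative import classify_cohort

__all__ = [
    "SITES", "TIMEPOINTS", "SCORE_COLUMNS",
    "read_cohort", "packaged_cohort_path", "read_volume", "write_volume",
    "RunConfig", "run_pipeline", "compare_timepoints",
]

SITES = ("r_hand", "l_hand", "r_foot", "l_foot")
TIMEPOINTS = ("acute", "m3")
SCORE_COLUMNS = tuple(f"{tp}_{site}" for tp in TIMEPOINTS for site in SITES)

_MINUS = "−"  # Unicode minus occasionally found in published tables


def packaged_cohort_path() -> Path:
    """Path of the packaged patient-cohort fixture (the study's Table 2)."""
    return Path(resources.files("tddkit") / "data" / "table2_cohort.csv")


def read_cohort(path) -> pd.DataFrame:
    """Read a patient cohort CSV into a typed frame.

    Adds boolean side-difference columns ``sd_{timepoint}_{site}`` parsed
    from the ``side_diff`` token column.  Malformed numeric cells raise with
    the offending row and column named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("patient",) + SCORE_COLUMNS + ("lesion",)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns {missing}")
    if df.empty:
        warnings.warn(f"cohort file {path} has a header but no rows", stacklevel=2)
    for col in ("patient",) + SCORE_COLUMNS:
        cleaned = df[col].str.replace(_MINUS, "-", regex=False).str.strip()
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.isna() & (cleaned != "")
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"unparseable value {df.loc[row, col]!r} in column {col!r}, "
                f"row {row + 2} of {path}")
        df[col] = converted
    df["patient"] = df["patient"].astype(int)
    df[list(SCORE_COLUMNS)] = df[list(SCORE_COLUMNS)].astype(float)
    tokens = df.get("side_diff", pd.Series([""] * len(df))).fillna("")
    valid = {f"{tp}_{site}" for tp in TIMEPOINTS for site in SITES}
    for tp in TIMEPOINTS:
        for site in SITES:
            df[f"sd_{tp}_{site}"] = False
    for i, cell in tokens.items():
        for tok in str(cell).split(";"):
            tok = tok.strip()
            if not tok:
                continue
            if tok not in valid:
                raise ValueError(
                    f"unknown side_diff token {tok!r} in row {i + 2} of {path}")
            df.loc[i, f"sd_{tok}"] = True
    return df


def read_volume(path, kind: str = "labels") -> LabelVolume | LesionMask:
    """Load a NIfTI volume as a parcellation (``kind='labels'``) or a binary
    lesion mask (``kind='mask'``, values other than 0/1 rejected)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if kind == "labels":
        return LabelVolume(data, img.affine)
    if kind == "mask":
        return LesionMask(data, img.affine)
    raise ValueError("kind must be 'labels' or 'mask'")


def write_volume(volume: LabelVolume | LesionMask, path) -> None:
    data = volume.data.astype(np.int16)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def compare_timepoints(cohort: pd.DataFrame, site: str) -> dict:
    """Paired acute-vs-3-month comparison of relative scores, pooling left
    and right sides of one body site ('hand' or 'foot').  Differences are
    acute minus follow-up: positive mean difference = improvement."""
    if site not in ("hand", "foot"):
        raise ValueError("site must be 'hand' or 'foot'")
    pre = np.concatenate([cohort[f"acute_r_{site}"], cohort[f"acute_l_{site}"]])
    post = np.concatenate([cohort[f"m3_r_{site}"], cohort[f"m3_l_{site}"]])
    res = paired_t(pre, post)
    return {"site": site, "n_pairs": len(pre), "mean_diff": res.mean_diff,
            "t": res.t, "df": res.df, "p": res.p}


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`."""

    cohort: str = "packaged"         # path or "packaged" for the fixture
    timepoint: str = "m3"
    alpha: float = 0.05
    confidence: float = 0.95
    seed: int = 0
    out_dir: str = "tdd_report"
    parcellation: str | None = None  # NIfTI path; enables node mapping
    lesion_dir: str | None = None    # dir of {patient}.nii[.gz] masks
    criteria: dict = field(default_factory=dict)
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if not 0 < self.alpha < 1 or not 0 < self.confidence < 1:
            raise ValueError("alpha and confidence must lie in (0, 1)")
        if (self.parcellation is None) != (self.lesion_dir is None):
            raise ValueError("parcellation and lesion_dir must be given together")
        NodeCriteria(**self.criteria) if self.criteria else None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        unknown = set(obj) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**obj)

    def digest(self) -> str:
        """Hash of the analytic inputs (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items()
                  if k not in ("out_dir", "verbosity")}
        return hashlib.sha256(
            json.dumps(fields, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Classify -> associate -> compare-timepoints (-> map-nodes) and write
    TSV/JSON reports plus a log carrying the config hash and seed.

    Returns the report bundle as a dict; identical inputs give identical
    outputs (every stochastic element is seeded by ``config.seed``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = packaged_cohort_path() if config.cohort == "packaged" else config.cohort
    cohort = read_cohort(cohort_path)

    bundle: dict = {"config_hash": config.digest(), "seed": config.seed}
    try:
        classification = classify_cohort(cohort, config.timepoint)
        classification.to_csv(out / "classification.tsv", sep="\t", index=False)
        bundle["classification"] = {
            "n_patients": int(len(classification)),
            "n_abnormal": int(classification["abnormal"].sum()),
        }
    except Exception as exc:  # pragma: no cover - stage diagnostics
        raise RuntimeError(f"classification stage failed: {exc}") from exc

    try:
        assoc = target_area_association(cohort, config.timepoint, config.confidence)
        bundle["association"] = {
            "table": [[assoc.table.a, assoc.table.b], [assoc.table.c, assoc.table.d]],
            "fisher_p_one_sided": assoc.p,
            "odds_ratio_ci": [assoc.or_ci[0],
                              None if np.isinf(assoc.or_ci[1]) else assoc.or_ci[1]],
            "confidence": config.confidence,
        }
    except Exception as exc:
        raise RuntimeError(f"association stage failed: {exc}") from exc

    try:
        bundle["timepoint_comparison"] = {
            site: compare_timepoints(cohort, site) for site in ("hand", "foot")}
    except Exception as exc:
        raise RuntimeError(f"timepoint-comparison stage failed: {exc}") from exc

    if config.parcellation:
        try:
            parc = read_volume(config.parcellation, "labels")
            nodes, table = split_into_contiguous_nodes(parc)
            lesions = {}
            for _, rec in cohort.iterrows():
                pid = int(rec["patient"])
                for suffix in (".nii.gz", ".nii"):
                    p = Path(config.lesion_dir) / f"{pid}{suffix}"
                    if p.exists():
                        lesions[pid] = read_volume(p, "mask")
                        break
                else:
                    raise FileNotFoundError(f"no lesion mask for patient {pid}")
            criteria = NodeCriteria(**config.criteria) if config.criteria else NodeCriteria()
            matrix = build_matrix(lesions, nodes, table, criteria)
            scores = side_composite_scores(cohort, config.timepoint)
            results = node_symptom_test(matrix, scores, alpha=config.alpha)
            results.to_csv(out / "node_mapping.tsv", sep="\t", index=False)
            bundle["node_mapping"] = {
                "n_nodes": int(len(table)),
                "analyzable_nodes": [int(n) for n in matrix.analyzable],
                "n_tests": int(len(results)),
                "significant": results.loc[results["reject"],
                                           ["node_id", "side"]].to_dict("records"),
            }
        except Exception as exc:
            raise RuntimeError(f"node-mapping stage failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1)
    with open(out / "run.log", "w") as fh:
        fh.write(f"tddkit pipeline\nconfig_hash: {config.digest()}\n"
                 f"seed: {config.seed}\nnumpy: {np.__version__}\n"
                 f"pandas: {pd.__version__}\n")
    return bundle
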