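"""Node-level lesion-symptom mapping.

Voxel-level mapping is hopeless when lesion locations barely overlap across
a small cohort, so the analysis is run at the level of "nodes": contiguous
sub-regions of a functional parcellation.  A parcellation volume is split
into connected components within each parent label; nodes then pass three
eligibility gates before any statistics are run:

  (i)   a node must have more than ``min_node_voxels`` voxels (default 100);
  (ii)  a patient counts as lesioned in a node when the lesion covers at
        least min(``overlap_abs``, ceil(``overlap_frac`` * node size))
        voxels of it (default min(100 voxels, 10% of the node));
  (iii) a node is analysed only when at least ``min_patients`` (default 4)
        patients are lesioned in it.

For each analysable node, lesioned and non-lesioned patients are compared on
composite side scores (left = left-hand + left-foot relative score, right
likewise) with a one-tailed two-sample t-test (lesioned worse, i.e. higher),
Holm-corrected across all node x side tests performed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cohort_stats import (ContingencyTable2x2, fisher_exact_one_sided,
                           fisher_or_ci, holm_bonferroni)
from .normative import classify_cohort

__all__ = [
    "LabelVolume",
    "LesionMask",
    "NodeCriteria",
    "NodeLesionMatrix",
    "split_into_contiguous_nodes",
    "eligible_nodes",
    "lesion_in_node",
    "build_matrix",
    "side_composite_scores",
    "node_symptom_test",
    "target_area_association",
    "annotation_mentions_target",
    "TARGET_AREA_PATTERN",
]


@dataclass
class LabelVolume:
    """Integer-labelled 3-D volume (0 = background) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("labels must be integers")
            self.data = np.round(self.data).astype(np.int32)
        if (self.data < 0).any():
            raise ValueError("labels must be nonnegative")
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be an invertible 4x4 transform")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_geometry(self, other: "LabelVolume | LesionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class LesionMask:
    """Binary lesion volume sharing the parcellation geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("lesion mask must be 3-D")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary 0/1; found values {vals[:10]}")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    same_geometry = LabelVolume.same_geometry


@dataclass(frozen=True)
class NodeCriteria:
    """Eligibility gates for node-level mapping (see module docstring)."""

    min_node_voxels: int = 100
    overlap_abs: int = 100
    overlap_frac: float = 0.10
    min_patients: int = 4

    def __post_init__(self) -> None:
        if min(self.min_node_voxels, self.overlap_abs, self.min_patients) <= 0:
            raise ValueError("criteria counts must be positive")
        if not 0 < self.overlap_frac <= 1:
            raise ValueError("overlap_frac must lie in (0, 1]")

    def required_overlap(self, node_size: int) -> int:
        """Minimum lesioned voxels inside a node: whichever is smaller of
        the absolute count and the (ceiling of the) fractional size."""
        return min(self.overlap_abs, ceil(self.overlap_frac * node_size))


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def split_into_contiguous_nodes(
    parcellation: LabelVolume,
    connectivity: int = 6,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Break every parcellation label into contiguous nodes.

    Connected-component labelling runs within each parent label separately
    (neighbouring voxels of different labels never join).  Nodes get stable
    ids 1..K ordered by parent label ascending, then component size
    descending (ties by first voxel in array order).  Returns the node label
    volume and a table (node_id, parent_label, n_voxels).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    node_data = np.zeros(parcellation.shape, np.int32)
    rows = []
    next_id = 1
    for parent in np.unique(parcellation.data):
        if parent == 0:
            continue
        comp, n_comp = ndimage.label(parcellation.data == parent, structure=structure)
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, n_comp + 1))
        # size-descending, first-occurrence tiebreak
        firsts = ndimage.minimum(
            np.arange(comp.size).reshape(comp.shape), comp, np.arange(1, n_comp + 1))
        for k in sorted(range(n_comp), key=lambda i: (-sizes[i], firsts[i])):
            node_data[comp == k + 1] = next_id
            rows.append({"node_id": next_id, "parent_label": int(parent),
                         "n_voxels": int(sizes[k])})
            next_id += 1
    table = pd.DataFrame(rows, columns=["node_id", "parent_label", "n_voxels"])
    return LabelVolume(node_data, parcellation.affine), table


def eligible_nodes(node_table: pd.DataFrame, criteria: NodeCriteria = NodeCriteria()) -> pd.DataFrame:
    """Nodes with strictly more than ``min_node_voxels`` voxels."""
    return node_table[node_table["n_voxels"] > criteria.min_node_voxels].reset_index(drop=True)


def lesion_in_node(
    lesion: LesionMask,
    nodes: LabelVolume,
    node_id: int,
    criteria: NodeCriteria = NodeCriteria(),
    node_size: int | None = None,
) -> bool:
    """Whether a lesion covers enough of a node to count (criterion ii).

    Geometries must already match; no resampling is ever done silently.
    """
    if not nodes.same_geometry(lesion):
        raise ValueError("lesion and node volume geometries differ (shape/affine)")
    in_node = nodes.data == node_id
    size = int(in_node.sum()) if node_size is None else int(node_size)
    if size == 0:
        raise ValueError(f"node {node_id} not present in volume")
    overlap = int((lesion.data & in_node).sum())
    return overlap >= criteria.required_overlap(size)


@dataclass
class NodeLesionMatrix:
    """Patients x nodes boolean lesion table over the eligible nodes."""

    matrix: pd.DataFrame            # index: patient id; columns: node_id
    node_table: pd.DataFrame        # eligible nodes with sizes
    analyzable: list = field(default_factory=list)  # node ids meeting criterion iii


def build_matrix(
    lesions: Mapping[object, LesionMask],
    nodes: LabelVolume,
    node_table: pd.DataFrame,
    criteria: NodeCriteria = NodeCriteria(),
) -> NodeLesionMatrix:
    """Apply criteria (i)-(iii): eligible nodes only, per-patient overlap
    rule, and the minimum-patients gate for analysability."""
    elig = eligible_nodes(node_table, criteria)
    sizes = dict(zip(elig["node_id"], elig["n_voxels"]))
    data = {}
    for pid, mask in lesions.items():
        data[pid] = {
            nid: lesion_in_node(mask, nodes, nid, criteria, node_size=sizes[nid])
            for nid in elig["node_id"]}
    mat = pd.DataFrame.from_dict(data, orient="index").reindex(columns=elig["node_id"])
    if mat.empty:
        mat = pd.DataFrame(columns=elig["node_id"])
    analyzable = [nid for nid in mat.columns if int(mat[nid].sum()) >= criteria.min_patients]
    return NodeLesionMatrix(matrix=mat, node_table=elig, analyzable=analyzable)


def side_composite_scores(cohort: pd.DataFrame, timepoint: str = "m3") -> pd.DataFrame:
    """Per-patient composite side scores at one time point: each side's
    hand + foot relative scores summed."""
    return pd.DataFrame({
        "patient": cohort["patient"],
        "left": cohort[f"{timepoint}_l_hand"] + cohort[f"{timepoint}_l_foot"],
        "right": cohort[f"{timepoint}_r_hand"] + cohort[f"{timepoint}_r_foot"],
    }).set_index("patient")


def node_symptom_test(
    matrix: NodeLesionMatrix,
    side_scores: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """One-tailed lesioned-vs-rest comparison of composite side scores for
    every analysable node, Holm-corrected over all tests performed.

    The alternative is that lesioned patients score higher (worse).  Pooled
    variance by default (df = n-2); Welch with ``equal_var=False``.  Nodes
    where either group has fewer than two patients are skipped with a
    warning.  Returns a frame with one row per (node, side) plus Holm
    critical alphas and rejection flags.
    """
    if not matrix.analyzable:
        raise ValueError("no analyzable nodes (criterion iii)")
    rows = []
    for nid in matrix.analyzable:
        lesioned = matrix.matrix.index[matrix.matrix[nid]]
        rest = matrix.matrix.index[~matrix.matrix[nid]]
        for side in ("left", "right"):
            g1 = side_scores.loc[lesioned, side].to_numpy(float)
            g0 = side_scores.loc[rest, side].to_numpy(float)
            if len(g1) < 2 or len(g0) < 2:
                warnings.warn(f"node {nid} ({side}): a group has <2 patients; skipped",
                              stacklevel=2)
                continue
            res = stats.ttest_ind(g1, g0, equal_var=equal_var, alternative="greater")
            df = (len(g1) + len(g0) - 2) if equal_var else float(res.df)
            rows.append({"node_id": nid, "side": side, "n_lesioned": len(g1),
                         "n_rest": len(g0), "t": float(res.statistic), "df": df,
                         "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no node/side test could be run")
    holm = holm_bonferroni(out["p"].to_numpy(), alpha=alpha)
    out["reject"] = holm.reject
    out["adjusted_p"] = holm.adjusted_p
    out["critical_alpha"] = holm.critical_alphas[np.argsort(np.argsort(out["p"].to_numpy(), kind="stable"), kind="stable")]
    return out


#: Target areas from prior functional-imaging work on tactile motion:
#: S1, S2 OP1, DLPFC, and the insular cortex (IC).  "internal capsule" is
#: always spelled out in annotations and never matches the IC token.
TARGET_AREA_PATTERN = re.compile(r"\b(S1|S2 OP1|DLPFC|IC)\b")


def annotation_mentions_target(annotation: str) -> bool:
    """Whether a free-text lesion annotation names a target area."""
    return bool(TARGET_AREA_PATTERN.search(annotation or ""))


class AssociationResult(NamedTuple):
    table: ContingencyTable2x2
    p: float
    or_ci: tuple


def target_area_association(
    cohort: pd.DataFrame,
    timepoint: str = "m3",
    confidence: float = 0.95,
) -> AssociationResult:
    """Target-lesion vs impairment 2x2 with one-sided Fisher p and the
    conditional exact odds-ratio CI.

    Patients lacking a lesion annotation are excluded with a warning.
    Impairment is the overall abnormality flag at ``timepoint``.
    """
    cohort = cohort.copy()
    missing = cohort["lesion"].isna() | (cohort["lesion"].astype(str).str.strip() == "")
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} patient(s) without lesion annotation",
            stacklevel=2)
        cohort = cohort[~missing]
    abnormal = classify_cohort(cohort, timepoint)["abnormal"].to_numpy()
    target = cohort["lesion"].map(annotation_mentions_target).to_numpy(bool)
    table = ContingencyTable2x2(
        a=int((target & abnormal).sum()), b=int((target & ~abnormal).sum()),
        c=int((~target & abnormal).sum()), d=int((~target & ~abnormal).sum()))
    p = fisher_exact_one_sided(table.as_array())
    degenerate = min(table.a + table.b, table.c + table.d,
                     table.a + table.c, table.b + table.d) == 0
    ci = (0.0, np.inf, confidence) if degenerate else fisher_or_ci(table.as_array(), confidence)
    return AssociationResult(table=table, p=p, or_ci=tuple(ci))
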