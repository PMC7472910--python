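"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* psychometric observers — probability of a correct direction judgement as
  a function of path length, logistic in log-distance with a 0.5 guessing
  floor (two-alternative forced choice) and a lapse rate; age degrades the
  observer's distance threshold multiplicatively;
* normative cohorts — healthy controls whose raw scores emerge from running
  the adaptive staircase on age-dependent observers, reproducing a roughly
  linear decline of discrimination with age on the foot and a floor effect
  on the hand;
* phantom parcellations and lesioned patient cohorts — label volumes with
  known component structure, lesion masks placed so that a designated
  "deficit node" is the only analysable one, and score shifts injected for
  patients lesioned there, with the ground truth returned for recovery
  tests.

Everything is bit-reproducible given a seed.  The packaged patient table
(the study's Table 2) is exposed via :func:`table2_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import SITES, packaged_cohort_path, read_cohort
from .lesion_mapping import LabelVolume, LesionMask
from .normative import NormativeSample
from .staircase import StaircaseConfig, expected_score_dp, run_staircase

__all__ = [
    "PsychometricObserver",
    "ObserverSpec",
    "PhantomSpec",
    "NodeShape",
    "simulate_normative_cohort",
    "simulate_patient_cohort",
    "SimulatedCohort",
    "make_phantom_parcellation",
    "table2_fixture",
]


@dataclass(frozen=True)
class PsychometricObserver:
    """P(correct | distance) for a simulated participant.

    ``alpha`` is the distance (mm) at the inflection of the underlying
    discrimination function, ``beta`` the slope on the log-distance axis,
    ``lapse`` the stimulus-independent error rate, and the guessing floor
    is fixed at 0.5 (forced choice between two directions).

    logistic form:  P(d) = 0.5 + (0.5 - lapse) * expit((ln d - ln alpha)/beta)
    weibull form:   P(d) = 0.5 + (0.5 - lapse) * (1 - exp(-(d/alpha)**(1/beta)))
    """

    alpha: float
    beta: float = 0.55
    lapse: float = 0.02
    form: str = "logistic"
    guess: float = field(default=0.5, init=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.form not in ("logistic", "weibull"):
            raise ValueError("form must be 'logistic' or 'weibull'")

    def __call__(self, distance: float) -> float:
        d = np.asarray(distance, float)
        if np.any(d <= 0):
            raise ValueError("distance must be positive")
        if self.form == "logistic":
            core = expit((np.log(d) - np.log(self.alpha)) / self.beta)
        else:
            core = 1.0 - np.exp(-((d / self.alpha) ** (1.0 / self.beta)))
        return float(self.guess + (0.5 - self.lapse) * core)


@dataclass(frozen=True)
class ObserverSpec:
    """Population of observers for one site with a multiplicative age effect.

    ``alpha0`` is the threshold distance of a reference-age participant,
    ``age_factor`` the proportional alpha increase per year of age (0.022 =
    2.2 %/year), and ``alpha_sigma`` the SD of the lognormal individual
    spread on alpha.  Defaults emulate the study's healthy controls: foot
    scores averaging ~40 with a ~1.2 points/year decline; hand observers
    have no age effect and sit near the floor of the score range.
    """

    alpha0: float
    age_factor: float = 0.0
    alpha_sigma: float = 0.35
    beta: float = 0.55
    lapse: float = 0.02
    ref_age: float = 22.0

    def observer(self, age: float, rng: np.random.Generator | None = None) -> PsychometricObserver:
        alpha = self.alpha0 * (1.0 + self.age_factor) ** (float(age) - self.ref_age)
        if rng is not None and self.alpha_sigma > 0:
            alpha *= float(np.exp(rng.normal(0.0, self.alpha_sigma)))
        return PsychometricObserver(alpha=alpha, beta=self.beta, lapse=self.lapse)


#: Site defaults (see docs/methods.md for the calibration rationale).
FOOT_OBSERVERS = ObserverSpec(alpha0=0.85, age_factor=0.052, alpha_sigma=0.35)
HAND_OBSERVERS = ObserverSpec(alpha0=0.60, age_factor=0.0, alpha_sigma=0.40)


def simulate_normative_cohort(
    site: str = "foot",
    n: int | None = None,
    age_range: tuple[int, int] = (22, 68),
    spec: ObserverSpec | None = None,
    seed: int | None = 0,
    config: StaircaseConfig = StaircaseConfig(),
) -> NormativeSample:
    """Healthy-control sample: ages drawn uniformly, observers built with
    the site's age-dependent sensitivity, raw scores produced by running
    the full adaptive staircase.  Default sizes match the study's normative
    groups (34 hand, 43 foot)."""
    if site not in ("hand", "foot"):
        raise ValueError("site must be 'hand' or 'foot'")
    if n is None:
        n = 43 if site == "foot" else 34
    if spec is None:
        spec = FOOT_OBSERVERS if site == "foot" else HAND_OBSERVERS
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    run_seeds = rng.integers(0, 2**31 - 1, size=n)
    scores = []
    for age, run_seed in zip(ages, run_seeds):
        obs = spec.observer(age, rng)
        scores.append(run_staircase(obs, config, seed=int(run_seed)).score)
    return NormativeSample(site=site, records=pd.DataFrame(
        {"age": ages, "sex": sexes, "raw_score": scores}))


def expected_score_at_age(site: str, age: float,
                          config: StaircaseConfig = StaircaseConfig()) -> float:
    """Noise-free expected staircase score of the site's median observer at
    a given age (individual alpha spread switched off)."""
    spec = FOOT_OBSERVERS if site == "foot" else HAND_OBSERVERS
    return expected_score_dp(spec.observer(age), config)


# ---------------------------------------------------------------------------
# Phantom parcellations and lesioned cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeShape:
    """One region of a phantom parcellation: an axis-aligned cuboid or a
    voxelized sphere carrying a parent label."""

    label: int
    kind: str = "cuboid"  # "cuboid" | "sphere"
    corner: tuple[int, int, int] = (0, 0, 0)   # cuboid: lowest-index corner
    size: tuple[int, int, int] = (1, 1, 1)     # cuboid edge lengths, voxels
    center: tuple[int, int, int] = (0, 0, 0)   # sphere
    radius: float = 1.0

    def fill(self, data: np.ndarray) -> np.ndarray:
        mask = np.zeros(data.shape, bool)
        if self.kind == "cuboid":
            sl = tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))
            stop = [c + s for c, s in zip(self.corner, self.size)]
            if min(self.corner) < 0 or any(t > n for t, n in zip(stop, data.shape)):
                raise ValueError(f"cuboid {self.corner}+{self.size} outside grid {data.shape}")
            mask[sl] = True
        elif self.kind == "sphere":
            grids = np.ogrid[tuple(slice(0, n) for n in data.shape)]
            r2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
            mask = r2 <= self.radius**2
            if not mask.any():
                raise ValueError("sphere covers no voxels")
        else:
            raise ValueError("kind must be 'cuboid' or 'sphere'")
        return mask


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.0
    nodes: tuple[NodeShape, ...] = ()


def make_phantom_parcellation(spec: PhantomSpec) -> LabelVolume:
    """Deterministic label volume from a list of non-overlapping shapes."""
    data = np.zeros(spec.shape, np.int32)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    for shape in spec.nodes:
        mask = shape.fill(data)
        if (data[mask] != 0).any():
            raise ValueError(f"shape with label {shape.label} overlaps an earlier shape")
        data[mask] = shape.label
    return LabelVolume(data, affine)


#: Default phantom: parent label 1 holds a large "deficit" component plus a
#: distant small one; label 2 holds a mid-sized component and a 64-voxel
#: fragment that fails the >100-voxel eligibility gate.
DEFAULT_PHANTOM = PhantomSpec(nodes=(
    NodeShape(label=1, corner=(4, 4, 4), size=(12, 12, 12)),    # 1728 vx, deficit node
    NodeShape(label=1, corner=(30, 30, 30), size=(6, 6, 6)),    # 216 vx
    NodeShape(label=2, corner=(4, 30, 4), size=(6, 6, 6)),      # 216 vx
    NodeShape(label=2, corner=(30, 4, 30), size=(4, 4, 4)),     # 64 vx, ineligible
))


class SimulatedCohort(NamedTuple):
    cohort: pd.DataFrame            # Table-2 dialect (plus an 'age' column)
    lesions: dict                   # patient id -> LesionMask
    parcellation: LabelVolume
    truth: dict                     # deficit placement ground truth


def simulate_patient_cohort(
    n_patients: int = 28,
    n_deficit_lesioned: int = 9,
    effect_sd: float = 1.5,
    baseline_mean: float = -0.2,
    baseline_sd: float = 0.3,
    deficit_side: str = "left",
    phantom: PhantomSpec = DEFAULT_PHANTOM,
    seed: int | None = 0,
) -> SimulatedCohort:
    """Patient cohort with lesions placed in a phantom parcellation.

    ``n_deficit_lesioned`` patients receive a lesion covering the large
    deficit component of parent label 1 (well past the overlap criterion);
    the rest get small lesions elsewhere that never reach sufficient
    overlap in any node, so exactly one node is analysable.  Patients
    lesioned in the deficit node have their ``deficit_side`` relative
    scores at both time points shifted up by ``effect_sd`` baseline SDs
    (contralateral deficit for a nominally right-hemisphere node; the side
    is configurable).  ``effect_sd=0`` yields a null cohort for
    calibration.  Relative scores are Gaussian around ``baseline_mean``
    (fast mode: the deficit acts on scores directly rather than through
    observer degradation).
    """
    if not 0 <= n_deficit_lesioned <= n_patients:
        raise ValueError("n_deficit_lesioned must lie in [0, n_patients]")
    if deficit_side not in ("left", "right", "bilateral"):
        raise ValueError("deficit_side must be 'left', 'right' or 'bilateral'")
    rng = np.random.default_rng(seed)
    parc = make_phantom_parcellation(phantom)
    deficit_shape = phantom.nodes[0]

    lesioned_ids = set(rng.choice(np.arange(1, n_patients + 1),
                                  size=n_deficit_lesioned, replace=False).tolist())
    lesions: dict[int, LesionMask] = {}
    rows = []
    shifted_sites = {
        "left": ("l_hand", "l_foot"), "right": ("r_hand", "r_foot"),
        "bilateral": SITES}[deficit_side]
    for pid in range(1, n_patients + 1):
        mask = np.zeros(phantom.shape, bool)
        if pid in lesioned_ids:
            # cover a 6x6x6 block inside the deficit component: 216 voxels,
            # past min(100, 10% of 1728 -> 173)
            c = tuple(x + 3 for x in deficit_shape.corner)
            mask[c[0]:c[0] + 6, c[1]:c[1] + 6, c[2]:c[2] + 6] = True
            annotation = "Right S2 OP1"
        else:
            # a small lesion in background near the far grid corner,
            # never reaching sufficient overlap with any node
            s0 = tuple(n - 4 for n in phantom.shape)
            mask[s0[0]:s0[0] + 3, s0[1]:s0[1] + 3, s0[2]:s0[2] + 3] = True
            annotation = "Right WM"
        lesions[pid] = LesionMask(mask.astype(np.uint8), parc.affine)

        rec = {"patient": pid, "age": int(rng.integers(29, 83)),
               "lesion": annotation, "side_diff": ""}
        for tp in ("acute", "m3"):
            for site in SITES:
                val = rng.normal(baseline_mean, baseline_sd)
                if pid in lesioned_ids and site in shifted_sites:
                    val += effect_sd * baseline_sd
                rec[f"{tp}_{site}"] = val
        rows.append(rec)
    cohort = pd.DataFrame(rows)
    for tp in ("acute", "m3"):
        for site in SITES:
            cohort[f"sd_{tp}_{site}"] = False
    truth = {"deficit_patients": sorted(lesioned_ids),
             "deficit_parent_label": deficit_shape.label,
             "deficit_component_voxels": int(np.prod(deficit_shape.size)),
             "deficit_side": deficit_side,
             "effect_sd": effect_sd}
    return SimulatedCohort(cohort=cohort, lesions=lesions, parcellation=parc,
                           truth=truth)


def table2_fixture() -> pd.DataFrame:
    """The study's patient table: 28 patients, eight relative TDD scores
    (acute and 3-month, right/left hand and foot), lesion annotations and
    side-difference flags, exactly as published."""
    return read_cohort(packaged_cohort_path())
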