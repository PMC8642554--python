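"""Synthetic ROI-volume cohorts with known ground-truth subtypes.

The generator emulates the structure of real regional-volume data from a
145-region atlas (119 gray-matter, 20 white-matter, 6 ventricle regions):
every subject shares non-disease-related variation — an age slope, a sex
offset, a per-subject global scale factor, low-rank correlated noise and
independent measurement noise, all multiplicative on a per-ROI baseline
volume — while patient subjects additionally express one of K subtype-specific
atrophy patterns: the ROIs of the subtype's mask are shrunk by a per-subject
atrophy fraction ``a`` (ventricle ROIs in a mask are enlarged by the same
fraction, since disease shows there as expansion).

Structural draws (per-ROI baseline means, the masks, the correlated-noise
loadings) come from a separate ``structure_seed``, so cohorts generated with
different ``seed`` values are replicates of the *same* underlying population
differing only in sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .io import ROI_PREFIX, ROITable

N_GM, N_WM, N_VENT = 119, 20, 6


@dataclass
class SyntheticCohortSpec:
    """Generative recipe for a CN reference group plus a patient group.

    Atrophy fractions are drawn per subject from Uniform[a_min, a_max].
    ``scale_sd`` is the SD of the log global scale factor — the dominant
    non-disease confound shared by both groups. Longitudinal fields control
    the two-pathway progression generator.
    """

    n_cn: int = 300
    n_pt_per_subtype: tuple[int, ...] = (134, 133, 133)
    n_gm: int = N_GM
    n_wm: int = N_WM
    n_vent: int = N_VENT
    mask_size: int = 15
    masks: tuple[tuple[int, ...], ...] | None = None  # default: disjoint GM masks
    allow_overlap: bool = False
    a_min: float = 0.1
    a_max: float = 0.3
    age_slope: float = -0.004  # relative volume change per year of age
    sex_offset: float = 0.04  # relative offset for sex == 1
    scale_sd: float = 0.1  # SD of log global scale factor
    lowrank_sd: float = 0.03  # per-factor loading scale, rank-5 shared noise
    noise_sd: float = 0.05  # independent relative measurement noise
    age_range: tuple[float, float] = (55.0, 85.0)
    # longitudinal
    pathway_mix: float = 0.7  # fraction routed through the first (early) mask
    n_visits: int = 6
    years_between_visits: float = 1.0
    speed_log_mean: float = float(np.log(0.06))  # atrophy fraction per year
    speed_log_sd: float = 0.5
    stage_entry_atrophy: float = 0.08  # atrophy at which a stage counts as entered
    late_onset_atrophy: float = 0.25  # early-mask atrophy at which the late mask starts
    atrophy_cap: float = 0.35
    seed: int = 0
    structure_seed: int = 20210101

    n_rois: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_rois = self.n_gm + self.n_wm + self.n_vent
        if not (0 <= self.a_min <= self.a_max < 1):
            raise ValueError("need 0 <= a_min <= a_max < 1")
        if self.masks is not None:
            for m in self.masks:
                if any(not 0 <= i < self.n_rois for i in m):
                    raise ValueError("mask indices out of range")
            if not self.allow_overlap:
                flat = [i for m in self.masks for i in m]
                if len(flat) != len(set(flat)):
                    raise ValueError("overlapping masks require allow_overlap=True")

    @property
    def k_true(self) -> int:
        return len(self.n_pt_per_subtype)

    @property
    def ventricle_indices(self) -> np.ndarray:
        return np.arange(self.n_gm + self.n_wm, self.n_rois)

    def resolved_masks(self) -> list[np.ndarray]:
        """The atrophy masks, drawing disjoint gray-matter masks if unset."""
        if self.masks is not None:
            return [np.asarray(m, dtype=int) for m in self.masks]
        rng = np.random.default_rng(self.structure_seed + 1)
        pool = rng.permutation(self.n_gm)
        need = self.k_true * self.mask_size
        if need > self.n_gm:
            raise ValueError("not enough GM ROIs for disjoint default masks")
        return [
            np.sort(pool[k * self.mask_size : (k + 1) * self.mask_size])
            for k in range(self.k_true)
        ]

    def baseline_means(self) -> np.ndarray:
        """Per-ROI baseline volumes, log-uniform on [2, 50] (arbitrary units)."""
        rng = np.random.default_rng(self.structure_seed)
        return np.exp(rng.uniform(np.log(2.0), np.log(50.0), self.n_rois))

    def _lowrank_loadings(self) -> np.ndarray:
        rng = np.random.default_rng(self.structure_seed + 2)
        return rng.normal(0.0, self.lowrank_sd, size=(self.n_rois, 5))


@dataclass
class GroundTruth:
    """Per patient-row bookkeeping aligned 1:1 with the generated rows."""

    data: pd.DataFrame  # columns: participant_id, subtype, atrophy, pathway, stage

    @property
    def subtype(self) -> np.ndarray:
        return self.data["subtype"].to_numpy()


def _roi_columns(n_rois: int) -> list[str]:
    return [f"{ROI_PREFIX}{i:03d}" for i in range(n_rois)]


def _shared_variation(spec: SyntheticCohortSpec, n: int, rng: np.random.Generator):
    """Draw the non-disease components for n subjects."""
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, n)
    sex = rng.integers(0, 2, n).astype(float)
    scale = np.exp(rng.normal(0.0, spec.scale_sd, n))
    factors = rng.normal(0.0, 1.0, size=(n, 5))
    eps = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_rois))
    return age, sex, scale, factors, eps


def _baseline_volumes(spec, age, sex, scale, factors, eps) -> np.ndarray:
    mean = spec.baseline_means()
    L = spec._lowrank_loadings()
    rel = (
        1.0
        + spec.age_slope * (age[:, None] - 70.0)
        + spec.sex_offset * sex[:, None]
        + factors @ L.T
        + eps
    )
    return mean[None, :] * scale[:, None] * rel


def _apply_atrophy(values: np.ndarray, mask: np.ndarray, a: np.ndarray, vent: np.ndarray) -> None:
    """Shrink masked tissue ROIs by a, enlarge masked ventricle ROIs by a."""
    is_vent = np.isin(mask, vent)
    tissue, ventm = mask[~is_vent], mask[is_vent]
    values[:, tissue] *= (1.0 - a)[:, None]
    if ventm.size:
        values[:, ventm] *= (1.0 + a)[:, None]


def generate_cross_sectional(spec: SyntheticCohortSpec) -> tuple[ROITable, GroundTruth]:
    """One baseline scan per subject: n_cn CN rows then the patient rows.

    Ground truth (subtype index and applied atrophy fraction) covers the
    patient rows, in table order.
    """
    rng = np.random.default_rng(spec.seed)
    masks = spec.resolved_masks()
    vent = spec.ventricle_indices
    n_pt = int(sum(spec.n_pt_per_subtype))

    age, sex, scale, factors, eps = _shared_variation(spec, spec.n_cn + n_pt, rng)
    values = _baseline_volumes(spec, age, sex, scale, factors, eps)

    subtype = np.repeat(np.arange(spec.k_true), spec.n_pt_per_subtype)
    a = rng.uniform(spec.a_min, spec.a_max, n_pt)
    pt_values = values[spec.n_cn :]  # view into values
    for k in range(spec.k_true):
        rows = np.flatnonzero(subtype == k)
        block = pt_values[rows].copy()
        _apply_atrophy(block, masks[k], a[rows], vent)
        pt_values[rows] = block

    pt_diag = rng.choice(["MCI", "Dementia"], n_pt)
    ids = [f"CN{i:04d}" for i in range(spec.n_cn)] + [f"PT{i:04d}" for i in range(n_pt)]
    df = pd.concat(
        [
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "visit_time": 0.0,
                    "diagnosis": ["CN"] * spec.n_cn + list(pt_diag),
                    "age": age,
                    "sex": sex,
                }
            ),
            pd.DataFrame(values, columns=_roi_columns(spec.n_rois)),
        ],
        axis=1,
    )
    gt = GroundTruth(
        pd.DataFrame(
            {
                "participant_id": ids[spec.n_cn :],
                "subtype": subtype,
                "atrophy": a,
                "pathway": -1,
                "stage": 1,
            }
        )
    )
    return ROITable(df), gt


def generate_longitudinal(spec: SyntheticCohortSpec) -> tuple[ROITable, GroundTruth]:
    """Patient subjects followed over visits along two progression pathways.

    Each subject is routed through mask 0 (pathway 0, with probability
    ``pathway_mix``) or mask 1 (pathway 1) and advances at a per-subject
    lognormal speed (atrophy fraction per year). Atrophy in the early mask
    grows linearly with time up to a cap; once it passes
    ``late_onset_atrophy`` the remaining masks start accumulating atrophy
    too, emulating a common advanced end-stage. Ground-truth stage per
    visit: 1 before the early mask passes ``stage_entry_atrophy``, 2 while
    only the early mask is affected, 3 once the late-stage atrophy passes
    the same entry threshold.
    """
    if spec.n_visits < 2:
        raise ValueError("need at least 2 visits")
    if spec.k_true < 2:
        raise ValueError("longitudinal generation needs at least 2 masks")
    rng = np.random.default_rng(spec.seed)
    masks = spec.resolved_masks()
    vent = spec.ventricle_indices
    n = int(sum(spec.n_pt_per_subtype))

    pathway = (rng.random(n) >= spec.pathway_mix).astype(int)  # 0 or 1
    speed = np.exp(rng.normal(spec.speed_log_mean, spec.speed_log_sd, n))

    age0, sex, scale, factors, _ = _shared_variation(spec, n, rng)
    rows, gt_rows = [], []
    for v in range(spec.n_visits):
        t = v * spec.years_between_visits
        eps = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_rois))
        values = _baseline_volumes(spec, age0 + t, sex, scale, factors, eps)
        a_early = np.minimum(speed * t, spec.atrophy_cap)
        a_late = np.minimum(np.maximum(speed * t - spec.late_onset_atrophy, 0.0), spec.atrophy_cap)
        for p in (0, 1):
            sub = np.flatnonzero(pathway == p)
            block = values[sub]
            _apply_atrophy(block, masks[p], a_early[sub], vent)
            other = masks[1 - p]
            _apply_atrophy(block, other, a_late[sub], vent)
            values[sub] = block
        stage = np.where(
            a_late > spec.stage_entry_atrophy,
            3,
            np.where(a_early > spec.stage_entry_atrophy, 2, 1),
        )
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"PT{i:04d}",
                    "visit_time": t,
                    "diagnosis": "MCI",
                    "age": age0[i] + t,
                    "sex": sex[i],
                }
            )
            gt_rows.append(
                {
                    "participant_id": f"PT{i:04d}",
                    "subtype": pathway[i],
                    "atrophy": a_early[i],
                    "pathway": pathway[i],
                    "stage": int(stage[i]),
                    "visit_time": t,
                    "speed": speed[i],
                }
            )
        if v == 0:
            all_values = [values]
        else:
            all_values.append(values)

    df = pd.concat(
        [
            pd.DataFrame(rows),
            pd.DataFrame(np.concatenate(all_values, axis=0), columns=_roi_columns(spec.n_rois)),
        ],
        axis=1,
    )
    df = df.sort_values(["participant_id", "visit_time"], kind="stable").reset_index(drop=True)
    gt = pd.DataFrame(gt_rows).sort_values(
        ["participant_id", "visit_time"], kind="stable"
    ).reset_index(drop=True)
    return ROITable(df), GroundTruth(gt)


def stage_probabilities(gt: GroundTruth, n_patterns: int = 4, confidence: float = 0.9) -> pd.DataFrame:
    """Idealized pattern-probability trajectories implied by ground truth.

    Maps each visit's ground-truth stage to a simplex row: stage 1 loads on
    pattern 1, stage 2 on pattern 2 or 3 (by pathway), stage 3 on the last
    pattern. Useful for closed-loop checks of the event-table machinery
    without a trained model in the loop.
    """
    if n_patterns < 4:
        raise ValueError("stage probabilities need at least 4 patterns")
    n = len(gt.data)
    rest = (1.0 - confidence) / (n_patterns - 1)
    probs = np.full((n, n_patterns), rest)
    stage = gt.data["stage"].to_numpy()
    pathway = gt.data["pathway"].to_numpy()
    target = np.where(stage == 1, 0, np.where(stage == 2, 1 + pathway, n_patterns - 1))
    probs[np.arange(n), target] = confidence
    out = gt.data[["participant_id", "visit_time"]].copy()
    for j in range(n_patterns):
        out[f"P{j + 1}"] = probs[:, j]
    return out


def benchmark_against_baselines(
    spec: SyntheticCohortSpec,
    methods: tuple[str, ...] = ("subtypegan", "kmeans", "gmm"),
    n_replicates: int = 5,
    hp=None,
) -> pd.DataFrame:
    """ARI vs ground truth per method per replicate on fresh cohorts.

    Baselines cluster the raw patient volumes directly (no CN reference),
    which is how conventional unsupervised clustering would be applied; the
    GAN route runs the full preprocess + train pipeline.
    """
    from . import gan, preprocess  # local import to avoid cycles

    records = []
    for rep in range(n_replicates):
        rspec = replace(spec, seed=spec.seed + rep)
        table, gt = generate_cross_sectional(rspec)
        truth = gt.subtype
        k = rspec.k_true
        pt_raw = table.select_diagnosis("MCI", "Dementia")
        for method in methods:
            if method == "subtypegan":
                prepared, cov, norm = preprocess.preprocess(table)
                cn = prepared.select_diagnosis("CN")
                pt = prepared.select_diagnosis("MCI", "Dementia")
                use_hp = hp if hp is not None else gan.HyperParams(M=k)
                use_hp = gan.replace_hp(use_hp, M=k, seed=use_hp.seed + 31 * rep)
                model = gan.train(cn, pt, use_hp)
                labels = np.argmax(gan.predict_probabilities(model, pt).probs, axis=1)
            elif method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=10, random_state=rep).fit_predict(
                    pt_raw.values
                )
            elif method == "gmm":
                labels = GaussianMixture(
                    n_components=k, n_init=3, random_state=rep
                ).fit_predict(pt_raw.values)
            else:
                raise ValueError(f"unknown method {method!r}")
            records.append(
                {"method": method, "replicate": rep, "ari": adjusted_rand_score(truth, labels)}
            )
    return pd.DataFrame(records)
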