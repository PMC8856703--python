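"""Synthetic connectomes, ground-truth observables, and planted cohorts.

Everything the pipeline consumes can be generated here with known ground
truth: geometric connectomes with distance-dependent log-normal weights,
model-generated "empirical" FC/FCD at a known global coupling (recovery
targets for the parameter search), and subject cohorts with planted
group-level inhibitory-weight offsets and a planted linear brain-behaviour
relation, mirroring a comparison group plus two patient subgroups with and
without visible lesions.

The generator's defaults are the study conditions: group sizes 36/30/14
(comparison / lesion-negative / lesion-positive), a lesion-positive J offset
that is negative over cortex and positive subcortically, and a first
behaviour factor constructed so that lower regional inhibition predicts more
symptoms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .bold import bold_from_activity, remove_transient
from .connectome import Connectome, write_connectome
from .fic import tune_fic
from .fitting import SubjectParameters, derive_seed
from .observables import FCDMatrix, FCMatrix, fc_matrix, fcd_matrix
from .params import DMFParams, HemodynamicParams
from .simulate import simulate

__all__ = [
    "generate_connectome",
    "generate_ground_truth_observables",
    "EffectConfig",
    "SyntheticCohort",
    "generate_cohort",
]

GROUPS = ("comparison", "ct_mri_negative", "ct_mri_positive")
DEFAULT_SIZES = {"comparison": 36, "ct_mri_negative": 30, "ct_mri_positive": 14}

SPHERE_RADIUS_MM = 70.0  # ~140 mm head diameter
DISTANCE_DECAY_MM = 60.0
LOGNORM_MU = 0.0
LOGNORM_SIGMA = 0.5
MEAN_ROW_SUM = 0.2  # streamline-fraction scale after consensus thresholding
SUBCORTICAL_FRACTION = 14 / 96  # matches the 82 cortical / 14 subcortical split


def _region_table(n_regions: int, rng: np.random.Generator) -> pd.DataFrame:
    n_sub = max(1, int(round(SUBCORTICAL_FRACTION * n_regions)))
    is_sub = np.zeros(n_regions, dtype=bool)
    is_sub[-n_sub:] = True
    return pd.DataFrame(
        {
            "region_id": np.arange(n_regions),
            "label": [f"region_{i:03d}" for i in range(n_regions)],
            "hemisphere": ["left" if i % 2 == 0 else "right" for i in range(n_regions)],
            "is_subcortical": is_sub,
        }
    )


def _sphere_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(n - got, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        pts[got : got + len(keep)] = keep
        got += len(keep)
    return pts


def generate_connectome(
    n_regions: int,
    density: float = 0.3,
    seed: int = 0,
    *,
    radius_mm: float = SPHERE_RADIUS_MM,
    decay_mm: float = DISTANCE_DECAY_MM,
    lognorm_mu: float = LOGNORM_MU,
    lognorm_sigma: float = LOGNORM_SIGMA,
    mean_row_sum: float = MEAN_ROW_SUM,
    max_retries: int = 20,
    return_details: bool = False,
):
    """Geometric synthetic connectome with distance-decaying weights.

    Regions are placed uniformly in a sphere of ``radius_mm``; tract lengths
    are Euclidean distances; raw weights are symmetrized log-normal draws
    attenuated by exp(-distance/decay_mm), thresholded to keep the strongest
    ``density`` fraction of off-diagonal pairs, and globally rescaled so the
    mean row sum equals ``mean_row_sum``. The default of 0.2 matches the
    magnitude of streamline-fraction weights after consensus thresholding:
    each region then receives modest long-range drive, the coupling grid
    spans a dynamically stable regime, and hyperexcitation appears only
    beyond it. Disconnected draws are rejected and retried with a warning.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        pos = _sphere_points(n_regions, radius_mm, rng)
        diff = pos[:, None, :] - pos[None, :, :]
        lengths = np.linalg.norm(diff, axis=2)
        iu = np.triu_indices(n_regions, k=1)
        n_pairs = iu[0].size
        raw = np.zeros((n_regions, n_regions))
        raw[iu] = rng.lognormal(lognorm_mu, lognorm_sigma, size=n_pairs)
        raw = raw + raw.T  # one log-normal draw per undirected pair
        w = raw * np.exp(-lengths / decay_mm)
        np.fill_diagonal(w, 0.0)
        n_keep = max(n_regions - 1, int(round(density * n_pairs)))
        if n_keep < n_pairs:
            cutoff = np.sort(w[iu])[n_pairs - n_keep - 1]
            w[w <= cutoff] = 0.0
        n_comp, _ = connected_components((w > 0).astype(int), directed=False)
        if n_comp > 1:
            warnings.warn(
                f"draw {attempt} produced a disconnected graph; retrying"
            )
            continue
        scale = w.sum(axis=1).mean() / mean_row_sum
        w = w / scale
        conn = Connectome(
            weights=w, lengths=lengths, regions=_region_table(n_regions, rng)
        )
        if return_details:
            details = {
                "positions": pos,
                "scale": scale,
                "lognorm_mu": lognorm_mu,
                "lognorm_sigma": lognorm_sigma,
                "decay_mm": decay_mm,
            }
            return conn, details
        return conn
    raise RuntimeError(
        f"could not draw a connected graph at density {density} "
        f"after {max_retries} attempts"
    )


def generate_ground_truth_observables(
    connectome: Connectome,
    g_true: float,
    seed: int = 0,
    retained_duration_s: float = 120.0,
    *,
    params: DMFParams | None = None,
    hemo: HemodynamicParams | None = None,
    transient_cut_s: float = 80.0,
    tr_s: float = 2.0,
    window_length_s: float = 30.0,
    window_step_s: float = 4.0,
    fic_kwargs: dict | None = None,
) -> tuple[FCMatrix, FCDMatrix, SubjectParameters]:
    """Model-generated "empirical" observables at a known global coupling.

    Runs the full forward pipeline (FIC tuning, simulation, hemodynamics,
    transient removal, FC/FCD) at ``g_true`` and returns the observables
    together with the true (G, J), for scoring parameter recovery.
    """
    params = (params or DMFParams()).with_(G=float(g_true))
    fic = tune_fic(
        connectome, params, seed=derive_seed(seed, 0xF1C), **(fic_kwargs or {})
    )
    if not fic.converged:
        raise RuntimeError(
            f"FIC tuning unstable at g_true={g_true}; rate-error history: "
            f"{fic.history}"
        )
    duration_ms = (retained_duration_s + transient_cut_s) * 1000.0
    traj = simulate(
        connectome, params, fic.J, duration=duration_ms, seed=derive_seed(seed, 0x51)
    )
    bold = remove_transient(
        bold_from_activity(traj, hemo=hemo, tr=tr_s), transient_cut_s
    )
    fc = fc_matrix(bold)
    fcd = fcd_matrix(bold, window_length_s, window_step_s)
    return fc, fcd, SubjectParameters(g_star=float(g_true), J=fic.J)


@dataclass
class EffectConfig:
    """Planted effect sizes for synthetic cohorts.

    cortical_J_shift / subcortical_J_shift : offsets (nA) added to the
        lesion-positive group's cortical / subcortical inhibitory weights.
    behavior_slope : strength of the planted (negative) relation between the
        first behaviour factor and mean inhibition over the planted regions.
    behavior_noise_sd : SD of the noise added to the first behaviour factor.
    planted_regions : region indices carrying the brain-behaviour relation
        (None selects all cortical regions).
    latent_loading : SD of the shared subject-level factor loaded onto the
        planted regions' J (gives the planted relation a common cause).
    tuning_noise_sd : SD of the independent per-region, per-subject J noise
        emulating run-to-run inhibition-tuning variability.
    """

    cortical_J_shift: float = -0.15
    subcortical_J_shift: float = 0.15
    behavior_slope: float = 0.6
    behavior_noise_sd: float = 0.8
    planted_regions: np.ndarray | None = None
    latent_loading: float = 0.05
    tuning_noise_sd: float = 0.03
    coupling_load: float = 0.15  # baseline J response to G * row-strength


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth recorded."""

    connectomes: list[Connectome]
    group: np.ndarray
    g: np.ndarray
    J: np.ndarray  # subjects x regions, shifts included
    true_J_offsets: np.ndarray  # subjects x regions planted group offsets
    behavior: np.ndarray  # subjects x 2 standardized factor scores
    planted_regions: np.ndarray
    generator_config: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.group)

    @property
    def n_regions(self) -> int:
        return self.J.shape[1]

    def brain_matrix(self) -> np.ndarray:
        """Subjects x (n+1) matrix of model parameters (G then J), PLS-ready."""
        return np.column_stack([self.g, self.J])

    def write(self, out_dir: str | Path) -> None:
        """Write cohort tables, per-subject connectome bundles, and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ids = [f"sub-{i:03d}" for i in range(self.n_subjects)]
        pd.DataFrame(
            {
                "subject_id": ids,
                "group": self.group,
                "factor_symptoms": self.behavior[:, 0],
                "factor_age_cognition": self.behavior[:, 1],
            }
        ).to_csv(out / "cohort.tsv", sep="\t", index=False)
        params = pd.DataFrame(
            self.brain_matrix(),
            columns=["G"] + [f"J_{i:03d}" for i in range(self.n_regions)],
        )
        params.insert(0, "subject_id", ids)
        params.to_csv(out / "parameters.tsv", sep="\t", index=False)
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        for sid, conn in zip(ids, self.connectomes):
            write_connectome(conn, conn_dir / f"{sid}.zip")
        (out / "manifest.json").write_text(
            json.dumps(self.generator_config, indent=2, default=str)
        )


def generate_cohort(
    sizes: dict[str, int] | None = None,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
    *,
    n_regions: int = 16,
    density: float = 0.3,
    shared_connectome: bool = False,
) -> SyntheticCohort:
    """Generate a cohort with planted group and brain-behaviour effects.

    Baseline inhibitory weights emulate tuned-model output: 1.0 nA plus a
    coupling-load term (stronger global input needs stronger inhibition)
    plus subject/region noise; the lesion-positive group receives the
    configured cortical (negative) and subcortical (positive) offsets. The
    first behaviour factor is ``-slope * z(mean J over planted regions)``
    plus noise, so lower inhibition maps to more symptoms; the second factor
    is independent noise. Both factors are standardized. All ground truth
    (offsets, planted regions, config) is recorded on the cohort.
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    cfg = effect_config or EffectConfig()
    unknown = set(sizes) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    groups = np.concatenate([[g] * sizes.get(g, 0) for g in GROUPS])
    n_subjects = len(groups)
    base_conn = generate_connectome(n_regions, density, derive_seed(seed, 0xC0))
    connectomes = []
    for s in range(n_subjects):
        if shared_connectome:
            connectomes.append(base_conn)
        else:
            connectomes.append(
                generate_connectome(n_regions, density, derive_seed(seed, 0xC0, s + 1))
            )
    cortical = base_conn.cortical_mask
    if cfg.planted_regions is None:
        planted = np.flatnonzero(cortical)
    else:
        planted = np.asarray(cfg.planted_regions, dtype=int)
        if planted.size and (planted.min() < 0 or planted.max() >= n_regions):
            raise ValueError("planted region indices out of range")

    g = rng.uniform(1.4, 2.8, size=n_subjects)
    J = np.empty((n_subjects, n_regions))
    latent = rng.standard_normal(n_subjects)
    for s in range(n_subjects):
        strength = connectomes[s].weights.sum(axis=1)
        J[s] = (
            1.0
            + cfg.coupling_load * g[s] * strength
            + cfg.tuning_noise_sd * rng.standard_normal(n_regions)
        )
    J[:, planted] += cfg.latent_loading * latent[:, None]

    offsets = np.zeros_like(J)
    pos = groups == "ct_mri_positive"
    offsets[np.ix_(pos, np.flatnonzero(cortical))] = cfg.cortical_J_shift
    offsets[np.ix_(pos, np.flatnonzero(~cortical))] = cfg.subcortical_J_shift
    J = np.maximum(J + offsets, 0.001)

    mean_planted = J[:, planted].mean(axis=1) if planted.size else np.zeros(n_subjects)
    z_planted = (
        (mean_planted - mean_planted.mean()) / mean_planted.std()
        if mean_planted.std() > 0
        else np.zeros(n_subjects)
    )
    f1 = -cfg.behavior_slope * z_planted + cfg.behavior_noise_sd * rng.standard_normal(
        n_subjects
    )
    f2 = rng.standard_normal(n_subjects)
    behavior = np.column_stack([f1, f2])
    behavior = (behavior - behavior.mean(axis=0)) / behavior.std(axis=0)

    config = {
        "sizes": sizes,
        "seed": seed,
        "n_regions": n_regions,
        "density": density,
        "shared_connectome": shared_connectome,
        "effect_config": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(cfg).items()
        },
    }
    return SyntheticCohort(
        connectomes=connectomes,
        group=groups,
        g=g,
        J=J,
        true_J_offsets=offsets,
        behavior=behavior,
        planted_regions=planted,
        generator_config=config,
    )
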