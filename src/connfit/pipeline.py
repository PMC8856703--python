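"""End-to-end orchestration: per-subject fitting and group analyses.

``RunConfig`` gathers every tunable of the pipeline (paths, model overrides,
grid, resampling counts, seeds) with two scale presets: ``fast`` for
continuous-integration sized runs (16 regions, short simulations, small
grid) and ``paper`` for demonstration-scale runs (96 regions, full grid,
full-length simulations). Every output directory receives a JSON manifest
recording the configuration hash and all seeds needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bold import BoldSeries, read_bold
from .connectome import Connectome, read_connectome
from .fitting import (
    GlobalCouplingSearch,
    SubjectParameters,
    qc_screen,
)
from .io import save_pse_store
from .observables import fc_matrix, fcd_matrix
from .params import DMFParams
from .pls import BehavioralPLS, MeanCenteredPLS, compare_saliences

logger = logging.getLogger("connfit")

__all__ = ["RunConfig", "run_subject_fit", "run_group_analysis"]

_PRESETS = {
    "fast": dict(
        n_regions=16,
        grid_min=1.4,
        grid_max=2.8,
        grid_n=5,
        n_iterations=2,
        sim_duration_ms=200_000.0,
        n_perm=100,
        n_boot=100,
    ),
    "paper": dict(
        n_regions=96,
        grid_min=1.4,
        grid_max=2.8,
        grid_n=50,
        n_iterations=20,
        sim_duration_ms=500_000.0,
        n_perm=1000,
        n_boot=1000,
    ),
}


@dataclass
class RunConfig:
    """Pipeline configuration; unspecified fields come from the scale preset."""

    scale: str = "fast"
    out_dir: str = "connfit_out"
    seed: int = 0
    grid_min: float | None = None
    grid_max: float | None = None
    grid_n: int | None = None
    n_iterations: int | None = None
    sim_duration_ms: float | None = None
    transient_cut_s: float = 80.0
    tr_s: float = 2.0
    window_length_s: float = 30.0
    window_step_s: float = 4.0
    n_perm: int | None = None
    n_boot: int | None = None
    n_regions: int | None = None
    model_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")
        for key, value in _PRESETS[self.scale].items():
            if getattr(self, key) is None:
                setattr(self, key, value)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def g_grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.grid_n)

    def dmf_params(self) -> DMFParams:
        return DMFParams(**self.model_params)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stable_subject_key(subject_id: str) -> int:
    """Process-independent integer key for a subject identifier.

    Python's built-in ``hash`` of strings is salted per process, which would
    silently break run-to-run reproducibility of derived seeds.
    """
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_subject_fit(
    config: RunConfig,
    subject_id: str,
    connectome: Connectome | str | Path,
    bold: BoldSeries | str | Path,
) -> SubjectParameters:
    """Fit one subject: observables -> grid search -> parameter extraction.

    Writes the search store (HDF5), the fitted parameter vector (TSV), and a
    manifest under ``config.out_dir/subject_id``.
    """
    if not isinstance(connectome, Connectome):
        p = Path(connectome)
        if not p.exists():
            raise FileNotFoundError(f"connectome file missing for {subject_id}: {p}")
        connectome = read_connectome(p)
    if not isinstance(bold, BoldSeries):
        p = Path(bold)
        if not p.exists():
            raise FileNotFoundError(f"BOLD file missing for {subject_id}: {p}")
        bold = read_bold(p, tr=config.tr_s)
    logger.info("subject %s: computing empirical observables", subject_id)
    emp_fc = fc_matrix(bold)
    emp_fcd = fcd_matrix(bold, config.window_length_s, config.window_step_s)
    logger.info("subject %s: running parameter space exploration", subject_id)
    est = GlobalCouplingSearch(
        g_grid=config.g_grid(),
        n_iterations=config.n_iterations,
        base_seed=config.seed,
        sim_duration_ms=config.sim_duration_ms,
        transient_cut_s=config.transient_cut_s,
        tr_s=config.tr_s,
        window_length_s=config.window_length_s,
        window_step_s=config.window_step_s,
        subject_id=_stable_subject_key(subject_id),
        params=config.dmf_params(),
    )
    est.fit(connectome, emp_fc, emp_fcd)
    out = Path(config.out_dir) / subject_id
    out.mkdir(parents=True, exist_ok=True)
    save_pse_store(est.store_, out / "pse_store.h5")
    vec = est.subject_parameters_.to_vector()
    names = ["G"] + [f"J_{i:03d}" for i in range(connectome.n_regions)]
    pd.DataFrame({"parameter": names, "value": vec}).to_csv(
        out / "parameters.tsv", sep="\t", index=False
    )
    _write_manifest(out, config, {"subject_id": subject_id, "g_star": est.g_star_})
    logger.info("subject %s: g* = %.4g", subject_id, est.g_star_)
    return est.subject_parameters_


def _pls_report(est, labels: list[str]) -> pd.DataFrame:
    rows = []
    for k, d in enumerate(est.singular_values_):
        rows.append(
            {
                "latent_variable": k + 1,
                "singular_value": d,
                "covariance_explained_pct": 100 * est.covariance_explained_[k],
                "perm_p": est.perm_pvalues_[k] if est.perm_pvalues_ is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_group_analysis(
    config: RunConfig,
    parameter_table: pd.DataFrame,
    cohort_table: pd.DataFrame,
    fit_table: pd.DataFrame | None = None,
) -> dict[str, dict]:
    """Run the configured group-level PLS analyses and the fit QC screen.

    ``parameter_table`` holds one row per subject (subject_id plus the
    parameter columns); ``cohort_table`` holds subject_id, group and the two
    behaviour factor columns. Emits per-analysis reports (singular values,
    covariance explained, permutation p, bootstrap ratios) under
    ``config.out_dir/group_analysis``.
    """
    merged = parameter_table.merge(cohort_table, on="subject_id", how="inner")
    if len(merged) != len(parameter_table):
        missing = set(parameter_table.subject_id) - set(cohort_table.subject_id)
        raise ValueError(f"subjects missing from cohort table: {sorted(missing)}")
    param_cols = [c for c in parameter_table.columns if c != "subject_id"]
    X = merged[param_cols].to_numpy(dtype=float)
    groups = merged["group"].to_numpy()
    behav_cols = [c for c in cohort_table.columns if c.startswith("factor_")]
    Y = merged[behav_cols].to_numpy(dtype=float)
    out = Path(config.out_dir) / "group_analysis"
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}

    if fit_table is not None:
        qc = qc_screen(
            fit_table["fc_fit"].to_numpy(), fit_table["fcd_ks"].to_numpy()
        )
        qc.insert(0, "subject_id", fit_table["subject_id"].to_numpy())
        qc.to_csv(out / "fit_qc.tsv", sep="\t", index=False)
        reports["fit_qc"] = {"table": qc}

    def _record(name, est):
        report = _pls_report(est, param_cols)
        report.to_csv(out / f"{name}_latent_variables.tsv", sep="\t", index=False)
        pd.DataFrame(
            est.bootstrap_ratios_, index=param_cols
        ).to_csv(out / f"{name}_bootstrap_ratios.tsv", sep="\t")
        reports[name] = {"estimator": est, "report": report}
        logger.info(
            "%s: singular values %s, perm p %s",
            name,
            np.round(est.singular_values_, 4),
            est.perm_pvalues_,
        )

    # omnibus 3-group and patient-vs-comparison 2-group contrasts
    mc_all = MeanCenteredPLS(
        n_perm=config.n_perm, n_boot=config.n_boot, random_state=config.seed
    ).fit(X, groups)
    _record("meancenter_3group", mc_all)
    patient = groups != "comparison"
    two_way = np.where(patient, "patient", "comparison")
    mc_two = MeanCenteredPLS(
        n_perm=config.n_perm, n_boot=config.n_boot, random_state=config.seed + 1
    ).fit(X, two_way)
    _record("meancenter_patient_vs_comparison", mc_two)

    # behavioural PLS: patients combined, then within each subgroup
    bp_all = BehavioralPLS(
        n_perm=config.n_perm, n_boot=config.n_boot, random_state=config.seed + 2
    ).fit(X[patient], Y[patient])
    _record("behavior_combined_patients", bp_all)
    within = {}
    for sub in ("ct_mri_negative", "ct_mri_positive"):
        mask = groups == sub
        if mask.sum() < 2:
            raise ValueError(
                f"within-group behavioural PLS needs >=2 subjects in {sub}, "
                f"found {mask.sum()}"
            )
        est = BehavioralPLS(
            n_perm=config.n_perm, n_boot=config.n_boot, random_state=config.seed + 3
        ).fit(X[mask], Y[mask])
        _record(f"behavior_within_{sub}", est)
        within[sub] = est

    # how much each subgroup drives the combined brain-behaviour pattern
    similarities = {}
    for sub, est in within.items():
        r, _ = compare_saliences(
            bp_all.brain_saliences_[:, 0], est.brain_saliences_[:, 0]
        )
        similarities[sub] = r
    pd.Series(similarities, name="salience_cosine").to_csv(
        out / "salience_similarity.tsv", sep="\t"
    )
    reports["salience_similarity"] = {"values": similarities}

    _write_manifest(out, config, {"n_subjects": int(len(merged))})
    return reports
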