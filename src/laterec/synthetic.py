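"""Synthetic multi-study breast-cancer cohort generator.

Generates probe-level log-scale expression compendia with the statistical
structure the downstream pipeline assumes:

* several studies whose batch structure is carried by latent factors loading
  on *all* probes, including a set of invariant control probes that carry no
  biology — the handle the harmonization stage uses;
* three receptor marker probes (ER, PR, HER2) drawn from two-component
  Gaussian mixtures conditional on a hidden receptor status that is only
  partially revealed through IHC labels;
* a four-subtype composition (Luminal A / Luminal B / HER2 type / TNBC)
  consistent with the receptor truth;
* planted prognostic probes whose effect on the recurrence hazard acts
  *only* before (early genes) or only at/after (late genes) a boundary,
  default five years — a piecewise-exponential dormancy-escape model;
* paired tumor-epithelium / stroma samples sharing a latent
  stromal-activation factor coupled to the epithelium's late-gene program.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence` spawning, so cohorts are bitwise
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLINICAL_COLUMNS, ExpressionMatrix, validate_clinical
from . import io as _io

__all__ = [
    "MarkerParams",
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

SUBTYPES = ("LumA", "LumB", "HER2type", "TNBC")
MARKERS = ("ER", "PR", "HER2")


@dataclass(frozen=True)
class MarkerParams:
    """Two-component Gaussian mixture for one receptor marker probe.

    ``prevalence`` is the marginal positive rate used to prior-weight the
    planted maximum-likelihood cutoff; ``ihc_fraction`` is the fraction of
    samples whose IHC label is observed.
    """

    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    prevalence: float
    ihc_fraction: float = 0.5


def _default_marker_params() -> dict[str, MarkerParams]:
    return {
        "ER": MarkerParams(5.0, 0.9, 9.0, 1.1, 0.70),
        "PR": MarkerParams(5.5, 0.9, 8.5, 1.2, 0.55),
        "HER2": MarkerParams(6.0, 0.7, 9.5, 1.3, 0.13),
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults are the study conditions."""

    n_studies: int = 4
    samples_per_study: int = 200
    n_probes: int = 1000
    n_control_probes: int = 69
    n_batch_factors: int = 3
    subtype_proportions: tuple = (0.70, 0.07, 0.06, 0.17)
    marker_params: dict = field(default_factory=_default_marker_params)
    n_early_genes: int = 40
    n_late_genes: int = 40
    #: inversely associated (good-prognosis) programs: genes whose
    #: expression falls with the latent risk factors, as in real prognostic
    #: probe sets where both directions of association occur
    n_early_inverse_genes: int = 20
    n_late_inverse_genes: int = 20
    early_loghr: float = 0.8
    late_loghr: float = 0.8
    boundary_years: float = 5.0
    followup_max_years: float = 15.0
    stroma_pairs: int = 46
    stroma_coupling: float = 0.8
    n_stromal_genes: int = 40
    #: the latent early/late risk factors are two-component mixtures: a
    #: background component plus a shifted high-risk subgroup, emulating the
    #: discrete expression subgroups with distinct prognosis
    risk_group_fraction: float = 0.25
    risk_group_shift: float = 2.2
    risk_background_sd: float = 0.5
    signal_loading: float = 0.9
    stromal_loading: float = 1.2
    batch_loading_sd: float = 0.5
    batch_score_sd: float = 1.0
    batch_within_sd: float = 0.3
    noise_sd: float = 0.5
    early_base_hazard: float = 0.045
    late_base_hazard: float = 0.035
    node_positive_fraction: float = 0.0
    treated_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies <= 0 or self.n_probes <= 0:
            raise ValueError("n_studies and n_probes must be positive")
        if self.samples_per_study < 0:
            raise ValueError("samples_per_study must be nonnegative")
        for name in (
            "n_control_probes", "n_batch_factors", "n_early_genes",
            "n_late_genes", "stroma_pairs", "n_stromal_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_control_probes >= self.n_probes:
            raise ValueError("n_control_probes must be < n_probes")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.shape != (4,) or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValueError("subtype_proportions must be a 4-vector summing to 1")
        if self.boundary_years <= 0 or self.followup_max_years <= 0:
            raise ValueError("time parameters must be positive")
        if not 0.0 <= self.stroma_coupling <= 1.0:
            raise ValueError("stroma_coupling must lie in [0, 1]")
        reserved = (
            len(MARKERS) + self.n_early_genes + self.n_late_genes
            + self.n_early_inverse_genes + self.n_late_inverse_genes
            + self.n_stromal_genes
        )
        if self.n_control_probes + reserved > self.n_probes:
            raise ValueError("not enough probes for markers and planted gene sets")


@dataclass
class CohortTruth:
    """Record of every planted quantity, for recovery checks."""

    early_probes: list
    late_probes: list
    early_inverse_probes: list
    late_inverse_probes: list
    stromal_probes: list
    marker_probes: dict
    marker_cutoffs: dict
    batch_loadings: pd.DataFrame
    batch_scores: pd.DataFrame
    u_early: pd.Series
    u_late: pd.Series
    stromal_factor: pd.Series
    receptor_truth: pd.DataFrame


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    truth: CohortTruth

    def __post_init__(self) -> None:
        if set(self.truth.early_probes) & set(self.truth.late_probes):
            raise ValueError("planted early and late probe sets overlap")
        if set(self.clinical.index) != set(self.expression.sample_ids):
            raise ValueError("clinical and expression samples disagree")


def _mixture_cutoff(mean_neg, sd_neg, mean_pos, sd_pos, prior_pos):
    """Expression value where prior-weighted class densities are equal.

    Solves the quadratic obtained by equating the two Gaussian log densities;
    the root between the class means is returned (see the receptor module
    for the estimation-side counterpart).
    """
    from .receptors import solve_cutoff

    return solve_cutoff(mean_neg, sd_neg, mean_pos, sd_pos, prior_pos)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort per ``spec``; deterministic given ``spec.seed``."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    (ss_sub, ss_mark, ss_batch, ss_sig, ss_surv, ss_stroma, ss_clin,
     ss_noise) = ss.spawn(8)
    rng_sub = np.random.default_rng(ss_sub)
    rng_mark = np.random.default_rng(ss_mark)
    rng_batch = np.random.default_rng(ss_batch)
    rng_sig = np.random.default_rng(ss_sig)
    rng_surv = np.random.default_rng(ss_surv)
    rng_stroma = np.random.default_rng(ss_stroma)
    rng_clin = np.random.default_rng(ss_clin)
    rng_noise = np.random.default_rng(ss_noise)

    # ----- identifiers ------------------------------------------------------
    n_bulk = spec.n_studies * spec.samples_per_study
    bulk_ids = [f"S{i + 1:05d}" for i in range(n_bulk)]
    bulk_study = np.repeat(
        [f"STUDY{j + 1:02d}" for j in range(spec.n_studies)], spec.samples_per_study
    )
    epi_ids = [f"E{i + 1:04d}" for i in range(spec.stroma_pairs)]
    str_ids = [f"T{i + 1:04d}" for i in range(spec.stroma_pairs)]
    pair_ids = [f"PR{i + 1:04d}" for i in range(spec.stroma_pairs)]
    mt_study = "STUDYMT"

    sample_ids = bulk_ids + epi_ids + str_ids
    tumor_ids = bulk_ids + epi_ids  # samples with epithelial tumor content
    n_tumor = len(tumor_ids)
    n_total = len(sample_ids)

    control_ids = [f"CTRL{i + 1:03d}" for i in range(spec.n_control_probes)]
    n_open = spec.n_probes - spec.n_control_probes
    open_ids = [f"P{i + 1:05d}" for i in range(n_open)]
    probe_ids = control_ids + open_ids

    pos = 0
    marker_probes = {m: open_ids[pos + k] for k, m in enumerate(MARKERS)}
    pos += len(MARKERS)
    early_probes = open_ids[pos:pos + spec.n_early_genes]
    pos += spec.n_early_genes
    late_probes = open_ids[pos:pos + spec.n_late_genes]
    pos += spec.n_late_genes
    early_inv_probes = open_ids[pos:pos + spec.n_early_inverse_genes]
    pos += spec.n_early_inverse_genes
    late_inv_probes = open_ids[pos:pos + spec.n_late_inverse_genes]
    pos += spec.n_late_inverse_genes
    stromal_probes = open_ids[pos:pos + spec.n_stromal_genes]
    pos += spec.n_stromal_genes
    background_probes = open_ids[pos:]

    gene_symbol = {}
    for pid in control_ids:
        gene_symbol[pid] = "CONTROL"
    gene_symbol[marker_probes["ER"]] = "ESR1"
    gene_symbol[marker_probes["PR"]] = "PGR"
    gene_symbol[marker_probes["HER2"]] = "ERBB2"
    for i, pid in enumerate(early_probes):
        gene_symbol[pid] = f"EARLY{i + 1:03d}"
    for i, pid in enumerate(late_probes):
        gene_symbol[pid] = f"LATE{i + 1:03d}"
    for i, pid in enumerate(early_inv_probes):
        gene_symbol[pid] = f"EARLYINV{i + 1:03d}"
    for i, pid in enumerate(late_inv_probes):
        gene_symbol[pid] = f"LATEINV{i + 1:03d}"
    for i, pid in enumerate(stromal_probes):
        gene_symbol[pid] = f"STROM{i + 1:03d}"
    for i, pid in enumerate(background_probes):
        gene_symbol[pid] = f"BG{i + 1:04d}"

    probe_annotation = pd.DataFrame(
        {
            "gene_symbol": [gene_symbol[p] for p in probe_ids],
            "is_control": [p in set(control_ids) for p in probe_ids],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # ----- subtype and receptor truth --------------------------------------
    props = np.asarray(spec.subtype_proportions, dtype=float)
    subtype_idx = rng_sub.choice(4, size=n_tumor, p=props)
    subtype = np.array(SUBTYPES)[subtype_idx]
    er = np.zeros(n_tumor, dtype=int)
    pr = np.zeros(n_tumor, dtype=int)
    her2 = np.zeros(n_tumor, dtype=int)
    luminal = (subtype == "LumA") | (subtype == "LumB")
    er[luminal] = rng_sub.random(luminal.sum()) < 0.90
    pr[luminal] = rng_sub.random(luminal.sum()) < 0.75
    neither = luminal & (er == 0) & (pr == 0)
    er[neither] = 1  # luminal requires ER+ and/or PR+
    her2[(subtype == "LumB") | (subtype == "HER2type")] = 1
    receptor_truth = pd.DataFrame(
        {"er": er, "pr": pr, "her2": her2, "subtype": subtype},
        index=pd.Index(tumor_ids, name="sample_id"),
    )

    # ----- latent risk and stromal factors ----------------------------------
    # mixture latents: background + a shifted high-risk subgroup, centered
    # and scaled to unit variance so loghr parameters stay per-SD effects
    def _mixture_latent():
        member = rng_sig.random(n_tumor) < spec.risk_group_fraction
        z = spec.risk_background_sd * rng_sig.standard_normal(n_tumor)
        z = z + spec.risk_group_shift * member
        f, s = spec.risk_group_fraction, spec.risk_group_shift
        mean = s * f
        var = spec.risk_background_sd**2 + s**2 * f * (1 - f)
        return (z - mean) / np.sqrt(var) if var > 0 else z

    u_early = _mixture_latent()
    u_late = _mixture_latent()
    u_early_s = pd.Series(u_early, index=tumor_ids, name="u_early")
    u_late_s = pd.Series(u_late, index=tumor_ids, name="u_late")
    c = spec.stroma_coupling
    v = c * u_late[n_bulk:] + np.sqrt(max(0.0, 1 - c * c)) * rng_stroma.standard_normal(
        spec.stroma_pairs
    )
    stromal_factor = pd.Series(v, index=str_ids, name="stromal_factor")

    # ----- expression -------------------------------------------------------
    baseline = rng_noise.normal(7.0, 1.0, size=spec.n_probes)
    x = np.tile(baseline[:, None], (1, n_total))
    x += rng_noise.normal(0.0, spec.noise_sd, size=(spec.n_probes, n_total))

    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    tumor_cols = np.arange(n_tumor)
    stroma_cols = np.arange(n_tumor, n_total)

    # batch factors: one loading vector per probe, per-study score means
    k = spec.n_batch_factors
    study_of_sample = np.concatenate(
        [bulk_study, np.repeat(mt_study, 2 * spec.stroma_pairs)]
    )
    studies = [f"STUDY{j + 1:02d}" for j in range(spec.n_studies)] + [mt_study]
    if k > 0:
        loadings = rng_batch.normal(0.0, spec.batch_loading_sd, size=(spec.n_probes, k))
        study_means = rng_batch.normal(0.0, spec.batch_score_sd, size=(len(studies), k))
        study_row = np.array([studies.index(s) for s in study_of_sample])
        scores = study_means[study_row] + rng_batch.normal(
            0.0, spec.batch_within_sd, size=(n_total, k)
        )
        x += loadings @ scores.T
    else:
        loadings = np.zeros((spec.n_probes, 0))
        scores = np.zeros((n_total, 0))
    batch_loadings = pd.DataFrame(
        loadings, index=probe_ids, columns=[f"F{j + 1}" for j in range(k)]
    )
    batch_scores = pd.DataFrame(
        scores, index=sample_ids, columns=[f"F{j + 1}" for j in range(k)]
    )

    # subtype effects on a third of background probes (tumor samples only)
    if background_probes:
        affected = rng_sig.random(len(background_probes)) < 0.3
        offsets = rng_sig.normal(0.0, 0.4, size=(len(background_probes), 4))
        offsets[~affected] = 0.0
        bg_rows = np.array([probe_pos[p] for p in background_probes])
        x[np.ix_(bg_rows, tumor_cols)] += offsets[:, subtype_idx]

    # marker mixtures (tumor samples)
    truth_status = {"ER": er, "PR": pr, "HER2": her2}
    marker_cutoffs = {}
    for m in MARKERS:
        p = spec.marker_params[m]
        row = probe_pos[marker_probes[m]]
        status = truth_status[m]
        vals = np.where(
            status == 1,
            rng_mark.normal(p.mean_pos, p.sd_pos, size=n_tumor),
            rng_mark.normal(p.mean_neg, p.sd_neg, size=n_tumor),
        )
        # marker probes replace baseline signal for tumor columns; batch kept
        x[row, tumor_cols] = vals + (loadings[row] @ scores[tumor_cols].T if k else 0.0)
        marker_cutoffs[m] = _mixture_cutoff(
            p.mean_neg, p.sd_neg, p.mean_pos, p.sd_pos, p.prevalence
        )

    # planted prognostic programs (tumor samples); inverse programs load
    # negatively on the same latent risk factors
    for probes, u, sign in (
        (early_probes, u_early, 1.0),
        (late_probes, u_late, 1.0),
        (early_inv_probes, u_early, -1.0),
        (late_inv_probes, u_late, -1.0),
    ):
        if probes:
            rows = np.array([probe_pos[p] for p in probes])
            x[np.ix_(rows, tumor_cols)] += sign * spec.signal_loading * u[None, :]

    # stromal activation program (stroma samples)
    if stromal_probes and spec.stroma_pairs:
        rows = np.array([probe_pos[p] for p in stromal_probes])
        x[np.ix_(rows, stroma_cols)] += spec.stromal_loading * v[None, :]
    # stroma tissue offset on background probes
    if spec.stroma_pairs and background_probes:
        bg_rows = np.array([probe_pos[p] for p in background_probes])
        tissue_shift = rng_stroma.normal(0.0, 0.5, size=len(background_probes))
        x[np.ix_(bg_rows, stroma_cols)] += tissue_shift[:, None]

    # ----- survival (piecewise-exponential, early/late gene windows) -------
    b = spec.boundary_years
    fmax = spec.followup_max_years
    h1 = spec.early_base_hazard * np.exp(spec.early_loghr * u_early)
    h2 = spec.late_base_hazard * np.exp(spec.late_loghr * u_late)
    e = rng_surv.exponential(1.0, size=n_tumor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_event = np.where(e < h1 * b, e / h1, b + (e - h1 * b) / h2)
    t_event = np.where(np.isfinite(t_event), t_event, np.inf)
    event = t_event <= fmax
    rfs_years = np.minimum(t_event, fmax)
    rfs_event = event.astype(int)
    distant = event & (rng_surv.random(n_tumor) < 0.75)
    recurrence_type = np.where(distant, "distant", np.where(event, "local", "none"))
    dmfs_years = np.where(distant, rfs_years, fmax)
    dmfs_event = distant.astype(int)
    death_lag = rng_surv.exponential(3.0, size=n_tumor)
    os_years = np.where(distant, np.minimum(rfs_years + death_lag, fmax), fmax)
    os_event = (distant & (rfs_years + death_lag <= fmax)).astype(int)

    # ----- clinical covariates ---------------------------------------------
    age = np.clip(rng_clin.normal(57.0, 12.0, size=n_tumor), 25.0, 90.0)
    size_cm = np.exp(rng_clin.normal(0.7 + 0.2 * u_early, 0.45))
    p_grade3 = 1.0 / (1.0 + np.exp(-(u_early - 0.3)))
    grade = np.where(
        rng_clin.random(n_tumor) < p_grade3,
        3,
        np.where(rng_clin.random(n_tumor) < 0.35, 1, 2),
    )
    node_status = (rng_clin.random(n_tumor) < spec.node_positive_fraction).astype(int)
    treated = (rng_clin.random(n_tumor) < spec.treated_fraction).astype(int)

    ihc = {}
    for m in MARKERS:
        frac = spec.marker_params[m].ihc_fraction
        observed = rng_clin.random(n_tumor) < frac
        lab = truth_status[m].astype(float)
        lab[~observed] = np.nan
        ihc[m] = lab

    tissue = np.array(
        ["bulk"] * n_bulk + ["epithelium"] * spec.stroma_pairs
    )
    pair_col = np.array([None] * n_bulk + pair_ids, dtype=object)
    clin_tumor = pd.DataFrame(
        {
            "study_id": study_of_sample[:n_tumor],
            "tissue": tissue,
            "pair_id": pair_col,
            "rfs_years": rfs_years,
            "rfs_event": rfs_event,
            "dmfs_years": dmfs_years,
            "dmfs_event": dmfs_event,
            "os_years": os_years,
            "os_event": os_event,
            "recurrence_type": recurrence_type,
            "node_status": node_status,
            "systemic_treated": treated,
            "size_cm": size_cm,
            "grade": grade,
            "age": age,
            "ihc_er": ihc["ER"],
            "ihc_pr": ihc["PR"],
            "ihc_her2": ihc["HER2"],
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    # stroma rows mirror the paired epithelium's outcomes; IHC not applicable
    if spec.stroma_pairs:
        clin_stroma = clin_tumor.loc[epi_ids].copy()
        clin_stroma.index = pd.Index(str_ids, name="sample_id")
        clin_stroma["tissue"] = "stroma"
        clin_stroma["pair_id"] = pair_ids
        clin_stroma[["ihc_er", "ihc_pr", "ihc_her2"]] = np.nan
        clinical = pd.concat([clin_tumor, clin_stroma])
    else:
        clinical = clin_tumor
    clinical = clinical.loc[sample_ids]
    validate_clinical(clinical)

    expression = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        probe_annotation,
        clinical[["study_id", "tissue", "pair_id"]].copy(),
    )
    truth = CohortTruth(
        early_probes=list(early_probes),
        late_probes=list(late_probes),
        early_inverse_probes=list(early_inv_probes),
        late_inverse_probes=list(late_inv_probes),
        stromal_probes=list(stromal_probes),
        marker_probes=dict(marker_probes),
        marker_cutoffs=marker_cutoffs,
        batch_loadings=batch_loadings,
        batch_scores=batch_scores,
        u_early=u_early_s,
        u_late=u_late_s,
        stromal_factor=stromal_factor,
        receptor_truth=receptor_truth,
    )
    return SyntheticCohort(expression, clinical, truth)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort to ``directory``; returns a manifest of the 3 data files.

    The truth record is written alongside (``truth_*.tsv``/``truth.json``)
    but is not part of the data manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "expression": str(directory / "expression.tsv"),
        "probes": str(directory / "probes.tsv"),
        "clinical": str(directory / "clinical.tsv"),
    }
    _io.write_expression(cohort.expression, manifest["expression"], manifest["probes"])
    _io.write_clinical(cohort.clinical, manifest["clinical"])

    t = cohort.truth
    samp = pd.concat(
        [
            t.u_early.rename("u_early"),
            t.u_late.rename("u_late"),
            t.stromal_factor.rename("stromal_factor"),
            t.batch_scores.add_prefix("score_"),
            t.receptor_truth.add_prefix("truth_"),
        ],
        axis=1,
    )
    samp.index.name = "sample_id"
    _io.write_table(samp, directory / "truth_samples.tsv")
    roles = pd.Series("background", index=cohort.expression.probe_ids, name="role")
    roles[cohort.expression.control_mask] = "control"
    roles[t.early_probes] = "early"
    roles[t.late_probes] = "late"
    roles[t.early_inverse_probes] = "early_inverse"
    roles[t.late_inverse_probes] = "late_inverse"
    roles[t.stromal_probes] = "stromal"
    for m, p in t.marker_probes.items():
        roles[p] = f"marker_{m}"
    probes = pd.concat([roles, t.batch_loadings.add_prefix("loading_")], axis=1)
    probes.index.name = "probe_id"
    _io.write_table(probes, directory / "truth_probes.tsv")
    with open(directory / "truth.json", "w") as fh:
        json.dump(
            {"marker_cutoffs": t.marker_cutoffs, "marker_probes": t.marker_probes},
            fh, indent=2,
        )
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    clinical = _io.read_clinical(directory / "clinical.tsv")
    expression = _io.read_expression(
        directory / "expression.tsv",
        directory / "probes.tsv",
        _io.sample_annotation_from_clinical(clinical),
    )
    samp = _io.read_table(directory / "truth_samples.tsv")
    probes = _io.read_table(directory / "truth_probes.tsv")
    with open(directory / "truth.json") as fh:
        meta = json.load(fh)
    score_cols = [c for c in samp.columns if c.startswith("score_")]
    load_cols = [c for c in probes.columns if c.startswith("loading_")]
    tumor = samp["u_early"].dropna().index
    truth = CohortTruth(
        early_probes=list(probes.index[probes["role"] == "early"]),
        late_probes=list(probes.index[probes["role"] == "late"]),
        early_inverse_probes=list(probes.index[probes["role"] == "early_inverse"]),
        late_inverse_probes=list(probes.index[probes["role"] == "late_inverse"]),
        stromal_probes=list(probes.index[probes["role"] == "stromal"]),
        marker_probes=meta["marker_probes"],
        marker_cutoffs=meta["marker_cutoffs"],
        batch_loadings=probes[load_cols].rename(columns=lambda c: c[8:]),
        batch_scores=samp[score_cols].rename(columns=lambda c: c[6:]),
        u_early=samp.loc[tumor, "u_early"],
        u_late=samp.loc[tumor, "u_late"],
        stromal_factor=samp["stromal_factor"].dropna(),
        receptor_truth=samp.loc[
            tumor, ["truth_er", "truth_pr", "truth_her2", "truth_subtype"]
        ].rename(columns=lambda c: c[6:]),
    )
    return SyntheticCohort(expression, clinical, truth)
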