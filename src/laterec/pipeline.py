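"""Configuration-driven end-to-end pipeline runner.

Stages (in order): ``synthesize`` (optional) -> ``harmonize`` ->
``receptors`` -> ``screen`` -> ``cluster`` -> ``stroma`` -> ``cascade`` ->
``validate``. Every stage writes tab-delimited outputs into the run
directory; a JSON manifest records the effective configuration, the seed,
package version and content hashes of every output, so a rerun with the
same configuration and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as _io
from .cluster import (
    cluster_category_enrichment,
    cluster_two_way,
    km_logrank,
    subtype_enrichment,
)
from .containers import ExpressionMatrix
from .epithelium import (
    CascadeCriteria,
    cascade_select,
    concordance_c4,
    timing_groups,
    validate_signature,
)
from .harmonize import confirm_mixing, fit_control_structure, remove_structure
from .receptors import call_receptors, fit_marker_model
from .stroma import PairedCompartmentSet, first_pc_score, stromal_de, trend_across_groups
from .survival import clinical_param_cox, screen_genome
from .synthetic import CohortSpec, generate_cohort, write_cohort

logger = logging.getLogger("laterec")

STAGES = [
    "synthesize",
    "harmonize",
    "receptors",
    "screen",
    "cluster",
    "stroma",
    "cascade",
    "validate",
]

#: Default marker -> gene symbol map used to locate marker probes.
MARKER_SYMBOLS = {"ER": "ESR1", "PR": "PGR", "HER2": "ERBB2"}


@dataclass
class PipelineConfig:
    """All pipeline parameters, with field-standard defaults.

    Exactly one of ``cohort_spec`` (synthesize a cohort) or the three input
    paths must be provided.
    """

    cohort_spec: CohortSpec = None
    expression_path: str = None
    probes_path: str = None
    clinical_path: str = None
    out_dir: str = "laterec_run"
    n_components: int = 40
    screen_threshold: float = 0.001
    endpoint: str = "rfs"
    boundary_years: float = 5.0
    k_samples: int = 4
    k_probes: int = 4
    stromal_fdr: float = 0.05
    r_min: float = 0.25
    cascade_de_fdr: float = 0.05
    cascade_cox_p: float = 0.01
    cascade_cox_scheme: str = "overall"
    long_followup_years: float = 15.0
    #: a subgroup must hold at least this fraction of clustered samples to
    #: be eligible as the late-enriched target (screens out outlier
    #: singletons produced by centroid linkage)
    target_min_group_fraction: float = 0.02
    marker_probes: dict = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = [self.expression_path, self.probes_path, self.clinical_path]
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.cohort_spec is not None and some_paths:
            raise ValueError("provide either a cohort spec or input paths, not both")
        if self.cohort_spec is None and not have_paths:
            raise ValueError(
                "provide either a cohort spec or all three input paths "
                "(expression, probes, clinical)"
            )
        for name in ("screen_threshold", "stromal_fdr", "cascade_de_fdr", "cascade_cox_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of range: {v}")
        if not 0.0 < self.r_min < 1.0:
            raise ValueError("r_min must lie in (0, 1)")
        if self.boundary_years <= 0 or self.long_followup_years <= 0:
            raise ValueError("time parameters must be positive")
        if self.k_samples < 1 or self.k_probes < 1:
            raise ValueError("cluster counts must be positive")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            spec = dataclasses.asdict(self.cohort_spec)
            spec["marker_params"] = {
                k: dataclasses.asdict(v) for k, v in self.cohort_spec.marker_params.items()
            }
            spec["subtype_proportions"] = list(self.cohort_spec.subtype_proportions)
            d["cohort_spec"] = spec
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic import MarkerParams

        d = dict(d)
        spec = d.get("cohort_spec")
        if spec is not None:
            spec = dict(spec)
            if "marker_params" in spec and spec["marker_params"] is not None:
                spec["marker_params"] = {
                    k: MarkerParams(**v) for k, v in spec["marker_params"].items()
                }
            if "subtype_proportions" in spec:
                spec["subtype_proportions"] = tuple(spec["subtype_proportions"])
            d["cohort_spec"] = CohortSpec(**spec)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunState:
    """Lazily loads stage outputs from the run directory."""

    def __init__(self, config: PipelineConfig, run_dir: Path):
        self.config = config
        self.run_dir = run_dir
        self._cache = {}

    def path(self, name: str) -> Path:
        return self.run_dir / name

    def clinical(self) -> pd.DataFrame:
        if "clinical" not in self._cache:
            if self.config.cohort_spec is not None:
                p = self.path("cohort/clinical.tsv")
            else:
                p = Path(self.config.clinical_path)
            self._cache["clinical"] = _io.read_clinical(p)
        return self._cache["clinical"]

    def raw_expression(self) -> ExpressionMatrix:
        if "raw" not in self._cache:
            if self.config.cohort_spec is not None:
                vp, pp = self.path("cohort/expression.tsv"), self.path("cohort/probes.tsv")
            else:
                vp, pp = self.config.expression_path, self.config.probes_path
            self._cache["raw"] = _io.read_expression(
                vp, pp, _io.sample_annotation_from_clinical(self.clinical())
            )
        return self._cache["raw"]

    def harmonized(self) -> ExpressionMatrix:
        if "harmonized" not in self._cache:
            self._cache["harmonized"] = _io.read_expression(
                self.path("harmonized.tsv"),
                self.path("cohort/probes.tsv")
                if self.config.cohort_spec is not None
                else self.config.probes_path,
                _io.sample_annotation_from_clinical(self.clinical()),
            )
        return self._cache["harmonized"]

    def set(self, key, value):
        self._cache[key] = value

    def table(self, name: str, key=None) -> pd.DataFrame:
        key = key or name
        if key not in self._cache:
            self._cache[key] = _io.read_table(self.path(name))
        return self._cache[key]


def _discovery_samples(clinical: pd.DataFrame) -> pd.Index:
    """Node-negative, systemically untreated bulk tumors."""
    m = (
        (clinical["tissue"] == "bulk")
        & (clinical["node_status"] == 0)
        & (clinical["systemic_treated"] == 0)
    )
    return clinical.index[m.fillna(False)]


def _late_event_share(clinical, sample_ids, endpoint, boundary):
    tcol, ecol = f"{endpoint}_years", f"{endpoint}_event"
    sub = clinical.loc[sample_ids]
    late = (sub[ecol] == 1) & (sub[tcol] >= boundary)
    return float(late.mean()) if len(sub) else 0.0


def run_pipeline(config: PipelineConfig, from_stage=None, to_stage=None) -> dict:
    """Execute the pipeline (or a contiguous stage subset) and write a manifest.

    ``from_stage``/``to_stage`` select a contiguous slice of
    :data:`STAGES`; upstream outputs must already exist in the run
    directory. Returns the manifest dict (also written to
    ``manifest.json``).
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)

    lo = STAGES.index(from_stage) if from_stage else 0
    hi = STAGES.index(to_stage) if to_stage else len(STAGES) - 1
    if lo > hi:
        raise ValueError("from_stage occurs after to_stage")
    selected = STAGES[lo:hi + 1]
    if config.cohort_spec is None and "synthesize" in selected:
        selected = [s for s in selected if s != "synthesize"]

    state = _RunState(config, run_dir)
    config.to_yaml(run_dir / "config.yaml")

    stage_meta = {}
    try:
        for stage in selected:
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            outputs = _STAGE_FUNCS[stage](config, state)
            dt = time.perf_counter() - t0
            logger.info("stage %s: done in %.2fs", stage, dt)
            stage_meta[stage] = {"outputs": [str(p) for p in outputs]}
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}. "
            f"Check inputs/parameters for this stage and rerun with "
            f"--from {stage}."
        ) from err
    finally:
        logger.removeHandler(fh)
        fh.close()

    hashes = {}
    for stage, meta in stage_meta.items():
        for p in meta["outputs"]:
            hashes[str(Path(p).relative_to(run_dir))] = _sha256(p)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {s: m["outputs"] for s, m in stage_meta.items()},
        "hashes": hashes,
    }
    with open(run_dir / "manifest.json", "w") as fhm:
        json.dump(manifest, fhm, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_synthesize(config, state):
    cohort = generate_cohort(config.cohort_spec)
    manifest = write_cohort(cohort, state.path("cohort"))
    state.set("clinical", cohort.clinical)
    state.set("raw", cohort.expression)
    return list(manifest.values())


def _stage_harmonize(config, state):
    x = state.raw_expression()
    k = min(config.n_components, int(x.control_mask.sum()), x.n_samples - 1)
    model = fit_control_structure(x, k)
    cleaned = remove_structure(x, model)
    stats = {"n_components": k}
    if x.sample_annotation["study_id"].nunique() >= 2:
        _, before = confirm_mixing(x)
        _, after = confirm_mixing(cleaned)
        stats.update(mixing_before=before, mixing_after=after)
    out = state.path("harmonized.tsv")
    cleaned.values.rename_axis("probe_id").to_csv(
        out, sep="\t", na_rep="NA", float_format="%.17g"
    )
    _io.write_table(model.component_scores, state.path("harmonization_scores.tsv"))
    with open(state.path("harmonization_stats.json"), "w") as fhj:
        json.dump(stats, fhj, indent=2)
    state.set("harmonized", cleaned)
    return [out, state.path("harmonization_scores.tsv"), state.path("harmonization_stats.json")]


def _marker_probe_map(config, x: ExpressionMatrix) -> dict:
    if config.marker_probes:
        return dict(config.marker_probes)
    sym = x.probe_annotation["gene_symbol"]
    out = {}
    for marker, symbol in MARKER_SYMBOLS.items():
        hits = sym.index[sym == symbol]
        if len(hits) == 0:
            raise KeyError(f"no probe annotated {symbol} for marker {marker}")
        out[marker] = hits[0]
    return out


def _stage_receptors(config, state):
    x = state.harmonized()
    clinical = state.clinical()
    probes = _marker_probe_map(config, x)
    tumor = clinical.index[clinical["tissue"].isin(["bulk", "epithelium"])]
    xt = x.subset_samples(tumor)
    ihc = clinical.loc[tumor, ["ihc_er", "ihc_pr", "ihc_her2"]]
    models = {}
    for marker, col in (("ER", "ihc_er"), ("PR", "ihc_pr"), ("HER2", "ihc_her2")):
        models[marker] = fit_marker_model(
            xt.values.loc[probes[marker]].to_numpy(),
            ihc[col].to_numpy(),
            marker=marker,
        )
    calls = call_receptors(xt, ihc, models, probes)
    out = state.path("receptor_calls.tsv")
    _io.write_table(calls.rename_axis("sample_id"), out)
    model_rows = pd.DataFrame(
        [dataclasses.asdict(m) for m in models.values()]
    ).set_index("marker")
    _io.write_table(model_rows, state.path("marker_models.tsv"))
    state.set("calls", calls)
    return [out, state.path("marker_models.tsv")]


def _stage_screen(config, state):
    x = state.harmonized()
    clinical = state.clinical()
    disc = _discovery_samples(clinical)
    if len(disc) == 0:
        raise ValueError("no discovery samples (node-negative, untreated bulk)")
    screen = screen_genome(
        x.subset_samples(disc),
        clinical,
        endpoint=config.endpoint,
        threshold=config.screen_threshold,
        boundary=config.boundary_years,
    )
    out = state.path("screen.tsv")
    _io.write_table(screen, out)
    state.set("screen", screen)

    # Clinical-parameter associations (early and late schemes)
    calls = state.table("receptor_calls.tsv", "calls")
    rows = []
    for param in ("her2", "er", "pr", "tnbc", "size", "grade", "age"):
        for scheme in ("early", "late"):
            try:
                res = clinical_param_cox(
                    clinical.loc[disc],
                    param,
                    scheme=scheme,
                    calls=calls,
                    endpoint=config.endpoint,
                    boundary=config.boundary_years,
                )
            except ValueError as err:
                logger.warning("clinical parameter %s/%s skipped: %s", param, scheme, err)
                continue
            rows.append({"parameter": param, "scheme": scheme, **res})
    _io.write_table(pd.DataFrame(rows), state.path("clinical_params.tsv"), index=False)
    return [out, state.path("clinical_params.tsv")]


def _stage_cluster(config, state):
    x = state.harmonized()
    clinical = state.clinical()
    screen = state.table("screen.tsv", "screen")
    selected = screen.index[screen["category"].isin(
        ["early-associated", "late-associated", "both"]
    )]
    if len(selected) < config.k_probes:
        raise ValueError(
            f"only {len(selected)} screen-selected probes; cannot form "
            f"{config.k_probes} probe clusters"
        )
    disc = _discovery_samples(clinical)
    epi = clinical.index[clinical["tissue"] == "epithelium"]
    cohort = disc.union(epi, sort=False)
    sub = x.subset_probes(selected).subset_samples(cohort)
    grouping = cluster_two_way(sub, config.k_samples, config.k_probes)

    groups_df = grouping.sample_groups.rename("group").rename_axis("sample_id")
    clusters_df = grouping.probe_clusters.rename("cluster").rename_axis("probe_id")
    _io.write_table(groups_df.to_frame(), state.path("sample_groups.tsv"))
    _io.write_table(clusters_df.to_frame(), state.path("probe_clusters.tsv"))

    # late-like target group = highest late-event share among groups of
    # non-trivial size
    sizes = grouping.sample_groups.value_counts()
    min_size = max(2, int(np.ceil(config.target_min_group_fraction * len(grouping.sample_groups))))
    shares = {
        g: _late_event_share(
            clinical, grouping.sample_groups.index[grouping.sample_groups == g],
            config.endpoint, config.boundary_years,
        )
        for g in grouping.sample_group_order
    }
    eligible = [g for g in shares if sizes.get(g, 0) >= min_size]
    if not eligible:
        eligible = list(shares)
    target = max(eligible, key=lambda g: shares[g])

    calls = state.table("receptor_calls.tsv", "calls")
    tab2 = subtype_enrichment(
        grouping.sample_groups, calls["subtype"].astype(str)
    )
    _io.write_table(tab2, state.path("subtype_enrichment.tsv"), index=False)
    tab3 = cluster_category_enrichment(
        grouping.probe_clusters, screen, config.screen_threshold
    )
    _io.write_table(tab3, state.path("cluster_enrichment.tsv"), index=False)

    km_rows = []
    for scheme in ("overall", "early", "late"):
        km = km_logrank(
            clinical, grouping.sample_groups, scheme,
            endpoint=config.endpoint, boundary=config.boundary_years,
        )
        km_rows.append({"scheme": scheme, "logrank_chi2": km.statistic, "p": km.p})
    _io.write_table(pd.DataFrame(km_rows), state.path("subgroup_survival.tsv"), index=False)

    with open(state.path("cluster_meta.json"), "w") as fhj:
        json.dump(
            {"target_group": target, "late_event_share": shares,
             "sample_inversions": grouping.sample_inversions,
             "probe_inversions": grouping.probe_inversions},
            fhj, indent=2, sort_keys=True,
        )
    state.set("groups", grouping.sample_groups)
    state.set("clusters", grouping.probe_clusters)
    state.set("target_group", target)
    return [
        state.path("sample_groups.tsv"), state.path("probe_clusters.tsv"),
        state.path("subtype_enrichment.tsv"), state.path("cluster_enrichment.tsv"),
        state.path("subgroup_survival.tsv"), state.path("cluster_meta.json"),
    ]


def _load_groups(state) -> pd.Series:
    if "groups" not in state._cache:
        df = state.table("sample_groups.tsv", "groups_df")
        state.set("groups", df["group"])
    return state._cache["groups"]


def _load_target(state) -> str:
    if "target_group" not in state._cache:
        with open(state.path("cluster_meta.json")) as fhj:
            state.set("target_group", json.load(fhj)["target_group"])
    return state._cache["target_group"]


def _stage_stroma(config, state):
    x = state.harmonized()
    pairs = PairedCompartmentSet.from_cohort(x)
    groups = _load_groups(state)
    target = _load_target(state)
    de = stromal_de(pairs, groups, target_group=target, fdr=config.stromal_fdr)
    _io.write_table(de, state.path("stromal_de.tsv"))
    chosen = de.index[de["selected"]]
    outputs = [state.path("stromal_de.tsv")]
    if len(chosen) >= 2:
        up = de.index[de["selected"] & (de["direction"] == "up")]
        stroma_ids = list(pairs.pairing.values())
        spc1 = first_pc_score(
            pairs.stroma.subset_samples(stroma_ids), chosen, name="SPC1", up_probes=up
        )
        sig = pd.DataFrame(
            {"loading": spc1.loadings,
             "direction": de.loc[spc1.probe_set, "direction"]}
        ).rename_axis("probe_id")
        _io.write_table(sig, state.path("spc1_signature.tsv"))
        _io.write_table(
            spc1.scores.rename("score").rename_axis("sample_id").to_frame(),
            state.path("spc1_scores.tsv"),
        )
        state.set("spc1", spc1)
        outputs += [state.path("spc1_signature.tsv"), state.path("spc1_scores.tsv")]
    else:
        logger.warning("stromal DE selected %d probes; SPC1 not computed", len(chosen))
    return outputs


def _stage_cascade(config, state):
    x = state.harmonized()
    pairs = PairedCompartmentSet.from_cohort(x)
    groups = _load_groups(state)
    target = _load_target(state)
    screen = state.table("screen.tsv", "screen")
    if "spc1" not in state._cache and not state.path("spc1_signature.tsv").exists():
        # stromal DE found nothing: the cascade signature is empty by
        # construction, recorded rather than raised
        logger.warning("no stromal signature; cascade signature is empty")
        empty = pd.DataFrame(
            {"r_spc1": np.nan, "de_t": np.nan, "de_q": np.nan,
             "cox_coef": np.nan, "cox_p": np.nan, "pass_r": False,
             "pass_de": False, "pass_cox": False, "selected": False},
            index=x.probe_ids.rename("probe_id"),
        )
        _io.write_table(empty, state.path("cascade.tsv"))
        return [state.path("cascade.tsv")]
    if "spc1" not in state._cache:
        sig = state.table("spc1_signature.tsv", "spc1_sig")
        scores = state.table("spc1_scores.tsv", "spc1_scores")["score"]
        from .stroma import MetageneScore

        state.set("spc1", MetageneScore(
            name="SPC1", probe_set=list(sig.index), loadings=sig["loading"],
            scores=scores, sign_anchor="loaded from run directory",
            explained_variance_ratio=float("nan"),
        ))
    criteria = CascadeCriteria(
        r_min=config.r_min, de_fdr=config.cascade_de_fdr,
        cox_p=config.cascade_cox_p, cox_scheme=config.cascade_cox_scheme,
    )
    cascade = cascade_select(
        pairs, state._cache["spc1"], groups, screen, criteria, target_group=target
    )
    _io.write_table(cascade, state.path("cascade.tsv"))
    signature = list(cascade.index[cascade["selected"]])
    outputs = [state.path("cascade.tsv")]
    clinical = state.clinical()
    tumor = clinical.index[clinical["tissue"].isin(["bulk", "epithelium"])]
    if len(signature) >= 2:
        epc1 = first_pc_score(x.subset_samples(tumor), signature, name="EPC1")
        _io.write_table(
            epc1.scores.rename("score").rename_axis("sample_id").to_frame(),
            state.path("epc1_scores.tsv"),
        )
        state.set("epc1", epc1)
        outputs.append(state.path("epc1_scores.tsv"))
    else:
        logger.warning("cascade produced %d probes; EPC1 not computed", len(signature))
    return outputs


def _stage_validate(config, state):
    clinical = state.clinical()
    if "epc1" not in state._cache and not state.path("epc1_scores.tsv").exists():
        logger.warning("no epithelial signature scores; validation skipped")
        with open(state.path("validation_summary.json"), "w") as fhj:
            json.dump({"note": "empty signature, nothing to validate"}, fhj)
        return [state.path("validation_summary.json")]
    if "epc1" not in state._cache:
        scores = state.table("epc1_scores.tsv", "epc1_scores")["score"]
    else:
        scores = state._cache["epc1"].scores
    tg = timing_groups(
        clinical, boundary=config.boundary_years,
        long_followup=config.long_followup_years, endpoint="dmfs",
    )
    report = validate_signature(scores, tg, clinical=clinical, endpoint="dmfs")
    _io.write_table(report.pairwise, state.path("validation_pairwise.tsv"), index=False)
    summary = {
        "anova_f": report.anova_f,
        "anova_p": report.anova_p,
        "group_medians": report.group_medians.to_dict(),
        "bin_medians": report.bin_medians.to_dict(),
        "timing_group_sizes": tg.value_counts().to_dict(),
    }
    outputs = [state.path("validation_pairwise.tsv")]

    # C4-analog concordance: probe cluster most enriched for late-direct genes
    try:
        tab3 = pd.read_csv(state.path("cluster_enrichment.tsv"), sep="\t")
        ld = tab3[(tab3["association"] == "late") & (tab3["direction"] == "direct")]
        c4_label = ld.set_index("cluster")["odds_ratio"].astype(float).idxmax()
        clusters = state.table("probe_clusters.tsv", "clusters_df")["cluster"]
        c4_probes = list(clusters.index[clusters == c4_label])
        cascade = state.table("cascade.tsv", "cascade")
        signature = list(cascade.index[cascade["selected"]])
        x = state.harmonized()
        tumor = clinical.index[clinical["tissue"].isin(["bulk", "epithelium"])]
        if len(c4_probes) >= 2 and len(signature) >= 2:
            _, _, r = concordance_c4(x.subset_samples(tumor), c4_probes, signature)
            summary["c4_label"] = str(c4_label)
            summary["c4_epc1_pearson_r"] = r
    except (FileNotFoundError, KeyError, ValueError) as err:
        logger.warning("C4 concordance skipped: %s", err)

    with open(state.path("validation_summary.json"), "w") as fhj:
        json.dump(summary, fhj, indent=2, sort_keys=True)
    outputs.append(state.path("validation_summary.json"))
    return outputs


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "harmonize": _stage_harmonize,
    "receptors": _stage_receptors,
    "screen": _stage_screen,
    "cluster": _stage_cluster,
    "stroma": _stage_stroma,
    "cascade": _stage_cascade,
    "validate": _stage_validate,
}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def make_report(run_dir, with_figures: bool = True) -> Path:
    """Render a human-readable summary of a completed run.

    Reads only the run directory's outputs; regenerating the report from
    the same directory produces identical content.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError("incomplete run: manifest.json missing")
    lines = ["# Pipeline report", ""]

    def table_section(title, name, max_rows=40):
        p = run_dir / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            lines.append(f"## {title}")
            lines.append("")
            lines.append(df.head(max_rows).to_string(index=False))
            lines.append("")

    table_section("Clinical parameters vs early/late recurrence", "clinical_params.tsv")
    table_section("Subtype distribution across subgroups", "subtype_enrichment.tsv")
    table_section("Screen-category enrichment across gene clusters",
                  "cluster_enrichment.tsv")
    table_section("Subgroup survival (log-rank)", "subgroup_survival.tsv")
    table_section("Signature validation (pairwise)", "validation_pairwise.tsv")

    cascade_path = run_dir / "cascade.tsv"
    if cascade_path.exists():
        casc = pd.read_csv(cascade_path, sep="\t")
        n_sel = int(casc["selected"].sum())
        if n_sel == 0:
            lines.append("**Cascade produced an empty signature.**")
        else:
            lines.append(f"**Cascade signature size: {n_sel} probes.**")
        lines.append("")

    summary_path = run_dir / "validation_summary.json"
    if summary_path.exists():
        with open(summary_path) as fhj:
            lines.append("## Validation summary")
            lines.append("")
            lines.append(json.dumps(json.load(fhj), indent=2, sort_keys=True))
            lines.append("")

    # conservation check: subgroup subtype counts sum to the cohort census
    sub_path = run_dir / "subtype_enrichment.tsv"
    if sub_path.exists():
        tab = pd.read_csv(sub_path, sep="\t")
        total = int(tab["n"].sum())
        lines.append(f"Total samples across subgroup/subtype cells: {total}")
        lines.append("")

    if with_figures:
        _report_figures(run_dir)
        lines.append("Figures: km_curves.png, score_trend.png (if inputs present)")
        lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


def _report_figures(run_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups_path = run_dir / "sample_groups.tsv"
    clin_path = run_dir / "cohort/clinical.tsv"
    if groups_path.exists() and clin_path.exists():
        clinical = _io.read_clinical(clin_path)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
        for ax, scheme in zip(axes, ("overall", "early", "late")):
            try:
                km = km_logrank(clinical, groups, scheme)
            except ValueError:
                continue
            for grp, curve in sorted(km.curves.items()):
                ax.step(curve["time"], curve["survival"], where="post", label=grp)
            ax.set_title(f"{scheme} (p={km.p:.2g})")
            ax.set_xlabel("years")
        axes[0].set_ylabel("recurrence-free fraction")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(run_dir / "km_curves.png", dpi=100)
        plt.close(fig)

    scores_path = run_dir / "epc1_scores.tsv"
    if scores_path.exists() and clin_path.exists():
        clinical = _io.read_clinical(clin_path)
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)["score"]
        tg = timing_groups(clinical)
        common = scores.index.intersection(tg.index)
        if len(common):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            order = [lab for lab in
                     ("no-recurrence", "early-metastasis", "late-metastasis")
                     if lab in set(tg.loc[common])]
            data = [scores.loc[common][tg.loc[common] == lab] for lab in order]
            ax.boxplot(data, tick_labels=order)
            ax.set_ylabel("EPC1 score")
            fig.tight_layout()
            fig.savefig(run_dir / "score_trend.png", dpi=100)
            plt.close(fig)
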