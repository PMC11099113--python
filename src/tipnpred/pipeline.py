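"""End-to-end orchestration of the staged prediction-model pipeline.

Per symptom: dichotomize the four-level self-report, split the cohort, run
variant QC, then build and evaluate the model stages in order —

    A1 (literature panel) -> B1 (scan + permutation FDR) ->
    B2 (wider scan + region tests + over-representation filter) ->
    C1 (B2 union literature-significant variants, collect VI) ->
    C2 (VI-pruned refit, cutoff tuned on training accuracy ~80%) -> accept/reject.

All selection (scan, FDR, gene tests, enrichment, VI, cutoff) sees only the
training cohort; the test cohort enters exactly once, at final evaluation.  All
randomness flows from a single master seed through fixed-order derived streams,
and the run report (JSON) is byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import evaluation as ev
from . import model_builder as mb
from . import region_tests as rt
from . import snv_association as sa
from .genotype_qc import GenotypeMatrix, QCThresholds, VariantRecord, filter_variants, read_vcf
from .synthetic_cohort import RESPONSE_LEVELS, SYMPTOMS

__all__ = ["RunConfig", "PipelineData", "dichotomize_symptom", "run_pipeline", "load_inputs"]


def dichotomize_symptom(responses: "pd.Series | np.ndarray") -> np.ndarray:
    """Map the four-level symptom report to moderate-severe (1) vs none-mild (0).

    "quite a bit" / "very much" -> 1; "not at all" / "a little" -> 0; missing
    (None, NaN, empty string) stays missing (NaN).  Any other value is an error.
    """
    arr = pd.Series(responses, dtype=object)
    out = np.full(len(arr), np.nan)
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            continue
        v = str(v).strip().lower()
        if v in RESPONSE_LEVELS[2:]:
            out[i] = 1.0
        elif v in RESPONSE_LEVELS[:2]:
            out[i] = 0.0
        else:
            raise ValueError(f"response {v!r} outside the 4-level scale")
    return out


@dataclass
class RunConfig:
    """Single configuration object for an end-to-end run."""

    # input paths (any may be None when data are passed in memory)
    vcf: str | None = None
    phenotypes: str | None = None
    panel: str | None = None  # literature panel TSV: variant_id, gene, source_p
    gmt: str | None = None
    out_dir: str | None = None

    symptoms: tuple[str, ...] = SYMPTOMS
    train_fraction: float = 0.7
    n_test: int | None = None
    seed: int = 0

    # stage parameters (defaults are the study's documented windows)
    n_permutations: int = 1000
    fdr_grid: tuple[float, ...] = sa.DEFAULT_THRESHOLD_GRID
    gene_p_threshold: float = 0.001
    b2_n_snvs: int = 400  # rank cutoff on scan best_p feeding B2
    ora_range_b2: tuple[float, float] = (0.005, 0.2)
    ora_range_c1: tuple[float, float] = (0.0025, 0.13)
    ora_grid_points: int = 5
    literature_p_max: float = 0.05  # panel variants carried into C1
    vi_grid: tuple[float, ...] = (1.0, 1.1, 1.25, 1.4, 1.5, 1.67)
    target_accuracy: float = 0.80
    epv_floor: float = 1.0
    n_boot: int = 500
    min_count: int = 5
    qc: QCThresholds = field(default_factory=QCThresholds)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        for key in ("symptoms", "fdr_grid", "vi_grid", "ora_range_b2", "ora_range_c1"):
            if key in raw:
                raw[key] = tuple(raw[key])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for s in cfg.symptoms:
            if s not in SYMPTOMS:
                raise ValueError(f"unknown symptom {s!r}; expected one of {SYMPTOMS}")
        return cfg


@dataclass
class PipelineData:
    """In-memory inputs to the pipeline."""

    matrix: GenotypeMatrix
    records: list[VariantRecord]
    phenotypes: pd.DataFrame  # covariates + <symptom> binary or <symptom>_response
    panel: pd.DataFrame | None = None  # variant_id, gene, source_p
    gene_sets: enr.GeneSetCollection | None = None


def load_inputs(config: RunConfig) -> PipelineData:
    matrix, records = read_vcf(config.vcf)
    pheno = pd.read_csv(config.phenotypes, index_col="sample_id")
    if list(pheno.index) != list(matrix.sample_ids):
        pheno = pheno.loc[matrix.sample_ids]
    panel = pd.read_csv(config.panel, sep="\t") if config.panel else None
    gene_sets = enr.read_gmt(config.gmt) if config.gmt else None
    return PipelineData(matrix, records, pheno, panel, gene_sets)


def _jsonify(obj):
    """Recursively coerce numpy scalars/arrays so reports serialize and compare."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _derived_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _outcome(pheno: pd.DataFrame, symptom: str) -> np.ndarray:
    col = symptom + "_response"
    if col in pheno.columns:
        return dichotomize_symptom(pheno[col])
    return pheno[symptom].to_numpy(dtype=float)


def _snv_gene_map(records: list[VariantRecord]) -> dict[str, set[str]]:
    return {r.variant_id: set(r.genes) for r in records}


def _ora_filter_with_search(
    candidate_snvs: set[str],
    records_by_id: dict[str, VariantRecord],
    gene_sets: enr.GeneSetCollection | None,
    p_range: tuple[float, float],
    n_points: int,
    fit_fn,
) -> tuple[set[str], float | None, float]:
    """Search the ORA p threshold inside ``p_range`` for the SNV subset whose
    refit model maximizes training AUC.  Without gene sets, returns the
    candidates untouched.  ``fit_fn(snvs) -> auc or None``."""
    if gene_sets is None or not candidate_snvs:
        auc = fit_fn(candidate_snvs)
        return candidate_snvs, None, auc if auc is not None else float("nan")
    snv_genes = {
        v: set(records_by_id[v].genes) for v in candidate_snvs if v in records_by_id
    }
    cand_genes = set().union(*snv_genes.values()) if snv_genes else set()
    grid = np.geomspace(p_range[0], p_range[1], n_points)
    best: tuple[float, set[str], float] | None = None
    for t in grid:
        _, _, kept_snvs, _ = enr.enrich_and_filter(
            cand_genes, gene_sets, float(t), snv_gene_map=snv_genes
        )
        if not kept_snvs:
            continue
        auc = fit_fn(kept_snvs)
        if auc is None:
            continue
        if best is None or auc > best[0] + 1e-12:
            best = (auc, kept_snvs, float(t))
    if best is None:
        auc = fit_fn(candidate_snvs)
        return candidate_snvs, None, auc if auc is not None else float("nan")
    return best[1], best[2], best[0]


def run_pipeline(
    config: RunConfig, data: PipelineData | None = None
) -> dict:
    """Execute every stage for every configured symptom; returns the run report.

    A stage error aborts that symptom's branch (recorded in the report); other
    symptoms continue.  When ``config.out_dir`` is set, the report, model JSONs
    and per-stage tables are written there.
    """
    if data is None:
        data = load_inputs(config)
    seeds = _derived_seeds(config.seed)
    seed_split, seed_fdr, seed_region, seed_boot = seeds[:4]

    # variant-level QC (genotype-only; outcome never enters)
    records, matrix, excl_log = filter_variants(data.records, data.matrix, config.qc)
    records_by_id = {r.variant_id: r for r in records}

    train_ids, test_ids = ev.split_cohort(
        matrix.sample_ids, config.train_fraction, seed=seed_split, n_test=config.n_test
    )
    m_train = matrix.subset_samples(train_ids)
    m_test = matrix.subset_samples(test_ids)
    pheno = data.phenotypes
    cov_cols = [c for c in mb.CLINICAL_COVARIATES if c in pheno.columns]
    covariates = pheno[cov_cols]

    report: dict = {
        "seed": config.seed,
        "n_samples": matrix.n_samples,
        "n_variants_input": data.matrix.n_variants,
        "n_variants_pass_qc": matrix.n_variants,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "symptoms": {},
    }

    panel_snvs: dict[str, str] = {}
    literature_sig: set[str] = set()
    if data.panel is not None:
        present = [v for v in data.panel["variant_id"] if v in records_by_id]
        panel_snvs = {v: "additive" for v in present}
        if "source_p" in data.panel.columns:
            sig = data.panel.loc[data.panel["source_p"] < config.literature_p_max, "variant_id"]
            literature_sig = {v for v in sig if v in records_by_id}

    for symptom in config.symptoms:
        try:
            report["symptoms"][symptom] = _run_symptom(
                symptom,
                config,
                m_train,
                m_test,
                train_ids,
                test_ids,
                pheno,
                covariates,
                records,
                records_by_id,
                panel_snvs,
                literature_sig,
                data.gene_sets,
                seed_fdr,
                seed_region,
                seed_boot,
            )
        except Exception as exc:  # a failing branch must not sink the others
            report["symptoms"][symptom] = {"error": f"{type(exc).__name__}: {exc}"}

    report = _jsonify(report)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        pd.DataFrame(excl_log, columns=["variant_id", "rule"]).to_csv(
            out / "qc_exclusions.tsv", sep="\t", index=False
        )
    return report


def _eval_stage(
    model: mb.FittedModel,
    m_train: GenotypeMatrix,
    m_test: GenotypeMatrix,
    covariates: pd.DataFrame,
    y_train: np.ndarray,
    y_test: np.ndarray,
    cutoff: float,
    n_boot: int,
    seed_boot: int,
) -> dict:
    p_train = model.predict(m_train, covariates)
    p_test = model.predict(m_test, covariates)
    rep_train = ev.evaluate(p_train, y_train, cutoff, "train", n_boot=n_boot, seed=seed_boot)
    rep_test = ev.evaluate(p_test, y_test, cutoff, "test", n_boot=n_boot, seed=seed_boot)
    return {
        "n_features": len(model.feature_names),
        "n_snvs": len(model.snv_codings),
        "dropped_singularities": model.dropped_singularities,
        "train": rep_train.to_dict(),
        "test": rep_test.to_dict(),
    }


def _run_symptom(
    symptom,
    config: RunConfig,
    m_train,
    m_test,
    train_ids,
    test_ids,
    pheno,
    covariates,
    records,
    records_by_id,
    panel_snvs,
    literature_sig,
    gene_sets,
    seed_fdr,
    seed_region,
    seed_boot,
) -> dict:
    y_all = _outcome(pheno, symptom)
    idx = {s: i for i, s in enumerate(pheno.index)}
    y_train = np.array([y_all[idx[s]] for s in train_ids])
    y_test = np.array([y_all[idx[s]] for s in test_ids])
    out: dict = {}

    def fit_stage(stage: str, snvs: dict[str, str], covs=mb.CLINICAL_COVARIATES):
        covs = tuple(c for c in covs if c in covariates.columns)
        return mb.build_model(
            stage, m_train, covariates, y_train, snvs, covs, epv_floor=config.epv_floor
        )

    def train_auc_for(snvs: set[str], scan=None) -> float | None:
        codings = {
            v: (scan.loc[v, "best_coding"] if scan is not None and v in scan.index else "additive")
            for v in snvs
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_stage("tmp", codings)
        except (mb.OverfitError, ValueError):
            return None
        return ev.roc_auc(m.train_predictions, y_train)

    # ----- A1: literature panel, additive coding -----
    if panel_snvs:
        try:
            a1 = fit_stage("A1", dict(panel_snvs))
            cutoff_a1 = ev.choose_cutoff(a1.train_predictions, y_train, config.target_accuracy)
            out["A1"] = _eval_stage(
                a1, m_train, m_test, covariates, y_train, y_test,
                cutoff_a1, config.n_boot, seed_boot,
            )
        except (mb.OverfitError, ValueError) as exc:
            out["A1"] = {"error": str(exc)}

    # ----- B1: scan + permutation FDR threshold -----
    scan = sa.snv_scan(m_train, y_train, min_count=config.min_count)
    curve = sa.permutation_fdr(
        m_train,
        y_train,
        n_perm=config.n_permutations,
        threshold_grid=config.fdr_grid,
        seed=seed_fdr,
        min_count=config.min_count,
    )
    b1_snvs = sa.select_snvs(scan, curve.chosen_threshold)
    out["B1"] = {
        "chosen_threshold": curve.chosen_threshold,
        "min_fdr": float(curve.fdr.min()),
        "n_snvs_selected": len(b1_snvs),
    }
    if b1_snvs:
        try:
            b1_codings = {v: scan.loc[v, "best_coding"] for v in b1_snvs}
            b1 = fit_stage("B1", b1_codings)
            cutoff_b1 = ev.choose_cutoff(b1.train_predictions, y_train, config.target_accuracy)
            out["B1"].update(
                _eval_stage(b1, m_train, m_test, covariates, y_train, y_test,
                            cutoff_b1, config.n_boot, seed_boot)
            )
        except (mb.OverfitError, ValueError) as exc:
            out["B1"]["error"] = str(exc)

    # ----- B2: wider scan inclusion + region tests + ORA filter -----
    wide = set(scan.nsmallest(config.b2_n_snvs, "best_p").index)
    region_df = rt.run_gene_tests(
        m_train,
        records,
        y_train,
        covariates=covariates.loc[train_ids].to_numpy(dtype=float),
        seed=seed_region,
    )
    sig_genes = rt.select_genes(region_df, config.gene_p_threshold)
    gene_snvs = {
        r.variant_id for r in records if r.genes & sig_genes
    }
    b2_cands = wide | gene_snvs
    b2_snvs, b2_thr, _ = _ora_filter_with_search(
        b2_cands, records_by_id, gene_sets, config.ora_range_b2,
        config.ora_grid_points, lambda s: train_auc_for(s, scan),
    )
    out["B2"] = {
        "n_candidates": len(b2_cands),
        "n_genes_significant": len(sig_genes),
        "ora_threshold": b2_thr,
        "n_snvs_selected": len(b2_snvs),
    }
    b2_codings = {
        v: (scan.loc[v, "best_coding"] if v in scan.index else "additive") for v in b2_snvs
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b2 = fit_stage("B2", b2_codings)
        cutoff_b2 = ev.choose_cutoff(b2.train_predictions, y_train, config.target_accuracy)
        out["B2"].update(
            _eval_stage(b2, m_train, m_test, covariates, y_train, y_test,
                        cutoff_b2, config.n_boot, seed_boot)
        )
    except (mb.OverfitError, ValueError) as exc:
        out["B2"]["error"] = str(exc)

    # ----- C1: B2 union literature-significant variants; tighter ORA window -----
    c1_cands = b2_snvs | literature_sig
    c1_snvs, c1_thr, _ = _ora_filter_with_search(
        c1_cands - literature_sig, records_by_id, gene_sets, config.ora_range_c1,
        config.ora_grid_points,
        lambda s: train_auc_for(s | literature_sig, scan),
    )
    c1_snvs = c1_snvs | literature_sig
    c1_codings = {
        v: (scan.loc[v, "best_coding"] if v in scan.index else "additive") for v in c1_snvs
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c1 = fit_stage("C1", c1_codings)
    out["C1"] = {
        "ora_threshold": c1_thr,
        "n_snvs": len(c1_snvs),
        "vi": {k: (v if np.isfinite(v) else 1e30) for k, v in sorted(c1.vi.items())},
    }

    # ----- C2: VI pruning, cutoff, final evaluation -----
    forced = tuple(c for c in ("paclitaxel", "bmi") if c in covariates.columns)
    vi_thr, c2 = mb.grid_search_vi_threshold(
        c1, m_train, covariates, y_train, config.vi_grid,
        forced_covariates=forced, epv_floor=config.epv_floor,
    )
    cutoff = ev.choose_cutoff(c2.train_predictions, y_train, config.target_accuracy)
    out["C2"] = {
        "vi_threshold": vi_thr,
        "cutoff": round(cutoff, 3),
        "snv_codings": dict(sorted(c2.snv_codings.items())),
    }
    out["C2"].update(
        _eval_stage(c2, m_train, m_test, covariates, y_train, y_test,
                    cutoff, config.n_boot, seed_boot)
    )
    out["C2"]["accepted"] = ev.accept_model(out["C2"]["train"]["auc"], out["C2"]["test"]["auc"])
    out["selected_features"] = {
        "B1": sorted(b1_snvs),
        "B2": sorted(b2_snvs),
        "C1": sorted(c1_snvs),
        "C2": sorted(c2.feature_names),
    }
    return out
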