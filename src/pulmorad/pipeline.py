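"""End-to-end orchestration: simulate -> extract -> QC -> search -> evaluate -> DCA.

Each run is a pure function of (config, seed): the synthetic cohort is
generated, features are extracted once per subject (one nodule per
subject), the panel is reduced by test-retest repeatability and redundancy,
candidate linear models are found by exhaustive search per size stratum and
feature category, the top model is evaluated on the held-out test cohort
against the longest-diameter and volume baselines, and decision curves
compare their clinical net benefit.  The manifest records the feature-count
waterfall and every headline number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .synthetic import (ClassDistribution, CohortConfig, generate_cohort,
                        generate_retest_pair, subject_table)
from .features import ExtractionSettings, descriptor_frame, extract_cohort
from .qc import qc_pipeline
from .discriminant import (LinearModel, evaluate_on_test, exhaustive_search,
                           fit_linear_discriminant, stratify_by_size)
from .dca import calibrate_scores, decision_curve
from . import io as pio

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; see docs/methods.md for rationale."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionSettings = field(default_factory=ExtractionSettings)
    seed: int = 0
    test_frac: float = 0.5
    n_retest_subjects: int = 40
    ccc_min: float = 0.7
    r2_min: float = 0.95
    max_dim: int = 4
    cv_repeats: int = 200
    train_frac: float = 0.8
    top_m: int = 5
    pool_cap: int | None = 60
    strata: tuple[str, ...] = ("all",)
    categories: tuple[str, ...] = ("all",)
    include_categories: tuple[str, ...] = ("C1", "C2", "C3")
    run_dca: bool = True
    dca_grid: tuple[float, float, float] = (0.01, 0.60, 0.01)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_frac < 1 or not 0 < self.train_frac < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if not -1 <= self.ccc_min <= 1 or not 0 <= self.r2_min <= 1:
            raise ValueError("thresholds out of range")
        if not 1 <= self.max_dim <= 4:
            raise ValueError("max_dim must be 1..4")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            c = dict(raw["cohort"])
            for key in ("malignant", "benign"):
                if key in c and isinstance(c[key], dict):
                    c[key] = ClassDistribution(**c[key])
            for key in ("grid_shape", "spacing_mm", "diameter_range"):
                if key in c:
                    c[key] = tuple(c[key])
            raw["cohort"] = CohortConfig(**c)
        if "extraction" in raw and isinstance(raw["extraction"], dict):
            e = dict(raw["extraction"])
            if "hu_clip" in e:
                e["hu_clip"] = tuple(e["hu_clip"])
            raw["extraction"] = ExtractionSettings(**e)
        for key in ("strata", "categories", "include_categories", "dca_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def demo_config(n_subjects: int = 100, seed: int = 0,
                heterogeneity_dominant: bool = True) -> PipelineConfig:
    """Desk-scale demonstration configuration.

    With ``heterogeneity_dominant`` the two classes share the same size
    distribution and differ mainly in internal texture (heterogeneity SD,
    airspace content, solid-core attenuation), so size baselines carry
    little signal and texture features must do the work.
    """
    if heterogeneity_dominant:
        malignant = ClassDistribution(
            diameter_mean=10.0, diameter_sd=2.5, spiculation_mean=0.10,
            spiculation_sd=0.03, core_hu_mean=-35.0, core_hu_sd=25.0,
            heterogeneity_sd_mean=70.0, heterogeneity_sd_sd=12.0,
            airspace_fraction_mean=0.07, airspace_fraction_sd=0.03)
        benign = ClassDistribution(
            diameter_mean=10.0, diameter_sd=2.5, spiculation_mean=0.10,
            spiculation_sd=0.03, core_hu_mean=-95.0, core_hu_sd=25.0,
            heterogeneity_sd_mean=30.0, heterogeneity_sd_sd=8.0,
            airspace_fraction_mean=0.01, airspace_fraction_sd=0.01)
        cohort = CohortConfig(n_per_class=n_subjects // 2, malignant=malignant,
                              benign=benign)
    else:
        cohort = CohortConfig(n_per_class=n_subjects // 2)
    return PipelineConfig(cohort=cohort, seed=seed, n_retest_subjects=30,
                          max_dim=3, cv_repeats=50, pool_cap=60)


@dataclass
class RunManifest:
    """Stage outputs and derived counts of one pipeline run."""

    seed: int
    version: str
    config_hash: str
    counts: dict
    results: list[dict]
    dca: list[dict]
    timings: dict

    def comparable(self) -> dict:
        """Manifest content with timings removed (determinism checks)."""
        return {"seed": self.seed, "version": self.version,
                "config_hash": self.config_hash, "counts": self.counts,
                "results": self.results, "dca": self.dca}


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def _model_payload(model: LinearModel, extra=None) -> dict:
    out = {"features": list(model.features),
           "weights": [float(w) for w in model.weights],
           "cutoff": float(model.cutoff),
           "train_auc": float(model.train_auc),
           "j_index": float(model.j_index)}
    if extra:
        out.update(extra)
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full workflow; returns the run manifest.

    Any stage failure aborts with a stage-tagged :class:`StageError`.
    """
    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in
             ("cohort", "clinical", "split", "retest", "search", "eval")}

    t0 = time.perf_counter()
    try:
        cohort = generate_cohort(config.cohort, seeds["cohort"])
        subjects = subject_table(cohort, seeds["clinical"])
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    timings["simulate"] = time.perf_counter() - t0

    y_all = subjects["label"].to_numpy()
    split_rng = np.random.default_rng(seeds["split"])
    test_mask = np.zeros(len(cohort), dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y_all == cls)
        split_rng.shuffle(idx)
        n_test = int(round(config.test_frac * len(idx)))
        test_mask[idx[:n_test]] = True

    t0 = time.perf_counter()
    try:
        table = extract_cohort([v for v, _ in cohort], config.extraction,
                               subjects.index.tolist())
    except Exception as exc:
        raise StageError("extract", exc) from exc
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        retest_rng = np.random.default_rng(seeds["retest"])
        train_ids = subjects.index[~test_mask]
        ids = list(train_ids[:config.n_retest_subjects])
        pairs = [generate_retest_pair(cohort[subjects.index.get_loc(i)][0].params,
                                      config.cohort,
                                      int(retest_rng.integers(0, 2**31 - 1)))
                 for i in ids]
        t_test = extract_cohort([a for a, _ in pairs], config.extraction, ids)
        t_retest = extract_cohort([b for _, b in pairs], config.extraction, ids)
        report, grouping, reduced, counts = qc_pipeline(
            t_test, t_retest, config.ccc_min, config.r2_min)
    except Exception as exc:
        raise StageError("qc", exc) from exc
    timings["qc"] = time.perf_counter() - t0

    descs = descriptor_frame(config.extraction)
    kept = [n for n in reduced.columns
            if descs.loc[n, "category"] in config.include_categories]
    if config.pool_cap is not None and len(kept) > config.pool_cap:
        dr = report.dynamic_range
        kept = sorted(sorted(kept), key=lambda n: -dr[n])[:config.pool_cap]
        kept = [n for n in reduced.columns if n in set(kept)]
    counts["pool"] = len(kept)

    train_table = table.loc[~test_mask, :]
    test_table = table.loc[test_mask, :]
    y_train = y_all[~test_mask]
    y_test = y_all[test_mask]
    diam_train = train_table["longest_diameter_mm"]
    diam_test = test_table["longest_diameter_mm"]

    results: list[dict] = []
    dca_rows: list[dict] = []
    search_rng = np.random.default_rng(seeds["search"])
    eval_rng = np.random.default_rng(seeds["eval"])

    t0 = time.perf_counter()
    for stratum in config.strata:
        tr = stratify_by_size(train_table, diam_train, stratum)
        te = stratify_by_size(test_table, diam_test, stratum)
        ytr = y_train[train_table.index.isin(tr.index)]
        yte = y_test[test_table.index.isin(te.index)]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            log.warning("stratum %s lacks both classes; skipped", stratum)
            continue
        for category in config.categories:
            pool = [n for n in kept
                    if category == "all" or descs.loc[n, "category"] == category]
            if not pool:
                log.warning("empty pool for stratum=%s category=%s", stratum,
                            category)
                continue
            try:
                sr = exhaustive_search(
                    tr, ytr, config.max_dim, pool, top_m=config.top_m,
                    seed=int(search_rng.integers(0, 2**31 - 1)),
                    cv_repeats=config.cv_repeats, train_frac=config.train_frac,
                    stratum=stratum, category=category)
            except Exception as exc:
                raise StageError("search", exc) from exc
            best, best_cv = sr.ranked[0]
            try:
                test_est = evaluate_on_test(
                    best, te, yte, repeats=200,
                    seed=int(eval_rng.integers(0, 2**31 - 1)))
                baselines = {}
                for bname in ("longest_diameter_mm", "volume_mm3"):
                    bmodel = fit_linear_discriminant(
                        tr[[bname]].to_numpy(), ytr, (bname,))
                    best_b = evaluate_on_test(
                        bmodel, te, yte, repeats=200,
                        seed=int(eval_rng.integers(0, 2**31 - 1)))
                    baselines[bname] = {"test_auc": best_b.auc_mean,
                                        "test_ci": list(best_b.auc_ci)}
            except Exception as exc:
                raise StageError("evaluate", exc) from exc
            results.append(_model_payload(best, {
                "stratum": stratum, "category": category,
                "search_space": sr.search_space_size,
                "cv_auc_mean": best_cv.auc_mean if best_cv else None,
                "cv_auc_ci": list(best_cv.auc_ci) if best_cv else None,
                "test_auc": test_est.auc_mean,
                "test_auc_ci": list(test_est.auc_ci),
                "test_sens": test_est.sens, "test_spec": test_est.spec,
                "baselines": baselines,
            }))
            if config.run_dca and category == "all":
                try:
                    risks = calibrate_scores(best.score(te), yte)
                    dmodel = fit_linear_discriminant(
                        tr[["longest_diameter_mm"]].to_numpy(), ytr,
                        ("longest_diameter_mm",))
                    drisks = calibrate_scores(dmodel.score(te), yte)
                    lo, hi, step = config.dca_grid
                    grid = np.round(np.arange(lo, hi + step / 2, step), 6)
                    dc = decision_curve({"radiomic": risks,
                                         "longest_diameter": drisks}, yte, grid)
                    dca_rows.append({
                        "stratum": stratum,
                        "prevalence": dc.prevalence,
                        "crossing_threshold": dc.crossing_threshold,
                        "mean_nb_radiomic": float(
                            dc.curves["radiomic"].mean()),
                        "mean_nb_diameter": float(
                            dc.curves["longest_diameter"].mean()),
                    })
                except Exception as exc:
                    raise StageError("dca", exc) from exc
    timings["search_evaluate_dca"] = time.perf_counter() - t0

    manifest = RunManifest(
        seed=config.seed, version=_version, config_hash=config.config_hash(),
        counts=counts, results=results, dca=dca_rows, timings=timings)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_table(table, out / "features.csv")
        pio.write_table(subjects, out / "subjects.csv")
        pio.write_table(report.frame(), out / "repeatability.csv")
        payload = {"seed": config.seed, "counts": counts,
                   "models": [_model_payload(
                       LinearModel(tuple(r["features"]),
                                   np.asarray(r["weights"]), r["cutoff"],
                                   r["train_auc"], r["j_index"])) for r in
                       results]}
        pio.write_results(payload, out / "results.json")
        (out / "manifest.json").write_text(json.dumps(
            {**manifest.comparable(), "timings": timings}, indent=2,
            default=pio._jsonable))
        config.to_yaml(out / "config.yaml")
    return manifest
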