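"""End-to-end orchestration: phantom → fitting → ROI histograms → statistics.

A run is configured by :class:`RunConfig` (either a phantom spec or paths to
real inputs), executes deterministically under one seed, and produces a
:class:`ReportBundle` of tables mirroring the standard reporting layout of a
two-class lesion study: per-lesion feature table, group-comparison table
(with significance stars * < 0.05, ** < 0.01, *** < 0.001), observer ICC
table, Spearman-vs-Gleason table, per-feature/combined-model ROC table and
a DeLong comparison of the pooled IVIM-kurtosis model against the ADC/MEM
model. Every table carries the seed and a config hash in a leading comment
line; reruns with identical config are byte-identical.

D, D* and ADC appear in all tables in ×10⁻³ mm²/s display units.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import cohort_stats as cs
from . import diagnostics as dx
from .exceptions import ConfigurationError, IvimKurtError, PlacementError, ValidationError
from .fitting import FitOptions, fit_maps
from .histogram import FEATURE_NAMES, summarize_roi
from .phantom import (
    DEFAULT_CLASSES,
    PhantomSpec,
    PhantomTruth,
    TissueClassSpec,
    generate_phantom,
)
from .series import BValueScheme, DWISeries, DEFAULT_SCHEME

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "simulate_observer",
    "PARAMS",
    "feature_columns",
]

logger = logging.getLogger("ivimkurt")

PARAMS = ("D", "Dstar", "f", "K", "ADC")
_DISPLAY_SCALE = {"D": 1e3, "Dstar": 1e3, "ADC": 1e3, "f": 1.0, "K": 1.0}
# Scale-dependent features; skewness/kurtosis are scale-free.
_SCALED_FEATURES = ("mean", "p10", "p25", "p50", "p75", "p90")


def feature_columns() -> list[str]:
    return [f"{p}_{f}" for p in PARAMS for f in FEATURE_NAMES]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``phantom`` (synthetic input) or ``dwi_path``+``mask_path``
    +``labels_path`` (real input) must be set. The seed governs phantom
    generation and observer-mask simulation and is recorded in every output.
    """

    phantom: PhantomSpec | None = None
    classes: tuple[TissueClassSpec, ...] = DEFAULT_CLASSES
    scheme: BValueScheme = DEFAULT_SCHEME
    dwi_path: str | None = None
    mask_path: str | None = None
    labels_path: str | None = None
    fit_options: FitOptions = field(default_factory=FitOptions)
    gate_alpha: float = 0.05
    icc_enabled: bool = True
    observer_jitter: float = 0.15
    intra_observer_jitter: float = 0.08
    fdr_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.dwi_path is not None
        if real == (self.phantom is not None):
            raise ConfigurationError(
                "exactly one of phantom spec or real-input paths must be set"
            )
        if real and (self.mask_path is None or self.labels_path is None):
            raise ConfigurationError("real input needs dwi, mask and labels paths")

    def config_hash(self) -> str:
        blob = repr(asdict(self)).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All tables of one run plus the run log."""

    lesion_features: pd.DataFrame
    group_table: pd.DataFrame
    icc_table: pd.DataFrame | None
    spearman_table: pd.DataFrame
    roc_table: pd.DataFrame
    roc_comparison: dict
    model_coefficients: dict
    log: list[str]
    seed: int
    config_hash: str

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# ivimkurt seed={self.seed} config={self.config_hash}\n"
        paths = {}

        def _csv(name: str, df: pd.DataFrame | None):
            if df is None:
                return
            p = outdir / f"{name}.csv"
            with open(p, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
            paths[name] = p

        _csv("lesion_features", self.lesion_features)
        _csv("group_comparison", self.group_table)
        _csv("icc", self.icc_table)
        _csv("spearman_gs", self.spearman_table)
        _csv("roc", self.roc_table)
        for name, obj in (
            ("roc_comparison", self.roc_comparison),
            ("model_coefficients", self.model_coefficients),
        ):
            p = outdir / f"{name}.json"
            payload = {"seed": self.seed, "config": self.config_hash, **obj}
            p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            paths[name] = p
        p = outdir / "run_log.txt"
        p.write_text(header + "\n".join(self.log) + "\n")
        paths["log"] = p
        return paths


def simulate_observer(mask: np.ndarray, perturbation: float, seed, max_tries: int = 10) -> np.ndarray:
    """A second observer's ROI: random boundary jitter of a lesion mask.

    Each outer-boundary voxel is added and each inner-boundary voxel removed
    independently with probability ``perturbation``. The result must be
    non-empty and overlap the original by ≥ 50%; bounded retries, then error.
    ``perturbation=0`` returns an identical mask. Deterministic given seed.
    Single-slice masks are jittered in-plane only (a human redraw stays on
    the chosen slice).
    """
    if perturbation < 0:
        raise ValidationError("perturbation must be >= 0")
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise ValidationError("empty mask")
    if perturbation == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    occupied_z = np.unique(np.argwhere(mask)[:, 2]) if mask.ndim == 3 else None
    if occupied_z is not None and occupied_z.size == 1:
        struct = struct.copy()
        struct[:, :, 0] = False
        struct[:, :, 2] = False
    n_mask = mask.sum()
    for _ in range(max_tries):
        outer = ndimage.binary_dilation(mask, struct) & ~mask
        inner = mask & ~ndimage.binary_erosion(mask, struct)
        new = mask.copy()
        new[outer] = rng.random(int(outer.sum())) < perturbation
        drop = rng.random(int(inner.sum())) < perturbation
        idx = np.argwhere(inner)[drop]
        new[tuple(idx.T)] = False
        overlap = (new & mask).sum()
        if new.any() and overlap / n_mask >= 0.5:
            return new
    raise PlacementError("observer jitter destroyed the ROI after retries")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _summarize_lesions(
    maps, labels_map: np.ndarray, lesions: pd.DataFrame, log: list[str],
    mask_per_lesion=None,
) -> pd.DataFrame:
    """Per-lesion feature table (display units) from fitted maps."""
    rows = []
    for _, lrow in lesions.iterrows():
        lid = int(lrow["lesion_id"])
        mask = mask_per_lesion(lid) if mask_per_lesion else (labels_map == lid)
        row = {
            "lesion_id": lid,
            "class": lrow["class_name"],
            "gleason": lrow.get("gleason"),
        }
        for p in PARAMS:
            arr = maps.get(p)
            summ = summarize_roi(arr, mask)
            if summ.n_dropped:
                log.append(f"lesion {lid} {p}: dropped {summ.n_dropped} missing voxels")
            for feat in FEATURE_NAMES:
                v = getattr(summ, feat)
                if feat in _SCALED_FEATURES:
                    v *= _DISPLAY_SCALE[p]
                row[f"{p}_{feat}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _group_comparison(features: pd.DataFrame, gate_alpha: float, log: list[str]) -> pd.DataFrame:
    is_pca = features["class"] == "PCa"
    rows = []
    for col in feature_columns():
        a = features.loc[is_pca, col].to_numpy()
        b = features.loc[~is_pca, col].to_numpy()
        res = cs.choose_and_run_group_test(a, b, alpha_gate=gate_alpha, feature=col)
        log.append(f"group test {col}: {res.test} (shapiro p={res.shapiro_p[0]:.3g}/"
                   f"{res.shapiro_p[1]:.3g}, levene p={res.levene_p:.3g})")
        param, feat = col.split("_", 1)
        rows.append(
            dict(
                parameter=param,
                feature=feat,
                pca_mean=a.mean(), pca_sd=a.std(ddof=1),
                bph_mean=b.mean(), bph_sd=b.std(ddof=1),
                test=res.test,
                statistic=res.statistic,
                df=res.df,
                p=res.pvalue,
                stars=_stars(res.pvalue),
            )
        )
    return pd.DataFrame(rows)


def _spearman_table(features: pd.DataFrame) -> pd.DataFrame:
    pca = features[features["class"] == "PCa"]
    gs = pca["gleason"].to_numpy(dtype=float)
    rows = []
    for col in feature_columns():
        v = pca[col].to_numpy(dtype=float)
        try:
            res = cs.spearman_gs(v, gs)
            rows.append(dict(feature=col, rho=res.rho, p=res.pvalue, n=res.n,
                             stars=_stars(res.pvalue)))
        except IvimKurtError:
            rows.append(dict(feature=col, rho=np.nan, p=np.nan, n=len(v), stars=""))
    return pd.DataFrame(rows)


def _observer_masks(truth: PhantomTruth, config: RunConfig) -> dict[str, dict[int, np.ndarray]]:
    """Deterministic simulated re-readings of every lesion ROI."""
    ss = np.random.SeedSequence([config.seed, 10_001])
    obs_seeds = ss.spawn(2 * len(truth.lesions))
    masks: dict[str, dict[int, np.ndarray]] = {"obs1": {}, "obs2": {}}
    for i, (_, lrow) in enumerate(truth.lesions.iterrows()):
        lid = int(lrow["lesion_id"])
        base = truth.mask(lid)
        masks["obs1"][lid] = simulate_observer(base, config.intra_observer_jitter, obs_seeds[2 * i])
        masks["obs2"][lid] = simulate_observer(base, config.observer_jitter, obs_seeds[2 * i + 1])
    return masks


def _icc_table(
    maps, truth: PhantomTruth, masks: dict, config: RunConfig, log: list[str]
) -> pd.DataFrame:
    """Simulated two-observer / repeat-reading ICC for the IVIM-kurtosis maps."""

    def _features_for(mask_of):
        return _summarize_lesions(maps, truth.labels, truth.lesions, log, mask_per_lesion=mask_of)

    feats = {
        "base": _features_for(lambda lid: truth.mask(lid)),
        "obs1": _features_for(lambda lid: masks["obs1"][lid]),
        "obs2": _features_for(lambda lid: masks["obs2"][lid]),
    }
    rows = []
    for p in ("D", "Dstar", "f", "K"):
        for feat in FEATURE_NAMES:
            col = f"{p}_{feat}"
            intra = cs.icc(
                np.column_stack([feats["base"][col], feats["obs1"][col]]), form="agreement"
            )
            inter = cs.icc(
                np.column_stack([feats["base"][col], feats["obs2"][col]]), form="agreement"
            )
            rows.append(
                dict(
                    parameter=p, feature=feat,
                    icc_intra=intra.value, category_intra=intra.category,
                    icc_inter=inter.value, category_inter=inter.category,
                )
            )
    return pd.DataFrame(rows)


def _roc_and_models(
    features: pd.DataFrame, group_table: pd.DataFrame, log: list[str]
) -> tuple[pd.DataFrame, dict, dict]:
    """Per-feature ROC for significant features plus combined logistic models."""
    is_pca = (features["class"] == "PCa").to_numpy()
    sig = group_table[group_table["p"] < 0.05]
    sig_cols = [f"{r.parameter}_{r.feature}" for r in sig.itertuples()]
    log.append(f"significant features ({len(sig_cols)}): {sig_cols}")

    rows = []

    def _row(name, roc: dx.ROCResult):
        rows.append(
            dict(
                name=name,
                auc=roc.auc, auc_lo=roc.auc_ci[0], auc_hi=roc.auc_ci[1],
                sensitivity_pct=100 * roc.sensitivity,
                sens_lo_pct=100 * roc.sensitivity_ci[0],
                sens_hi_pct=100 * roc.sensitivity_ci[1],
                specificity_pct=100 * roc.specificity,
                spec_lo_pct=100 * roc.specificity_ci[0],
                spec_hi_pct=100 * roc.specificity_ci[1],
                youden=roc.youden,
                criterion=roc.criterion,
            )
        )

    for col in sig_cols:
        _row(col, dx.roc_analysis(features[col].to_numpy(), is_pca))

    # Combined models: per-family significant features, the pooled
    # IVIM-kurtosis model, and the ADC/MEM model.
    family_specs = []
    for fam, label in (("D", "D model"), ("Dstar", "D* model"), ("K", "K model")):
        members = [c for c in sig_cols if c.split("_", 1)[0] == fam]
        if members:
            family_specs.append(dx.CombinedModelSpec(label, tuple(members)))
        else:
            log.append(f"no significant {fam} features; {label} skipped")
    ivim_members = [c for c in sig_cols if c.split("_", 1)[0] in ("D", "Dstar", "f", "K")]
    adc_members = [c for c in sig_cols if c.split("_", 1)[0] == "ADC"]
    if ivim_members:
        family_specs.append(dx.CombinedModelSpec("IVIM-kurtosis model", tuple(ivim_members)))
    if adc_members:
        family_specs.append(dx.CombinedModelSpec("ADC/MEM model", tuple(adc_members)))

    coefs = {}
    model_scores = {}
    for spec in family_specs:
        scores, roc, fitted = dx.fit_combined_model(features, is_pca, spec)
        _row(spec.name, roc)
        coefs[spec.name] = {
            "features": list(fitted.features),
            "coefficients": fitted.coefficients,
            "intercept": fitted.intercept,
        }
        model_scores[spec.name] = scores

    comparison = {}
    if "IVIM-kurtosis model" in model_scores and "ADC/MEM model" in model_scores:
        cmp = dx.delong_compare(
            model_scores["IVIM-kurtosis model"], model_scores["ADC/MEM model"], is_pca
        )
        comparison = {
            "model_a": "IVIM-kurtosis model",
            "model_b": "ADC/MEM model",
            "auc_a": cmp.auc_a,
            "auc_b": cmp.auc_b,
            "z": cmp.z,
            "p": cmp.pvalue,
            "degenerate": cmp.degenerate,
        }
        log.append(f"DeLong z={cmp.z:.3f} p={cmp.pvalue:.4f} degenerate={cmp.degenerate}")
    return pd.DataFrame(rows), comparison, coefs


def _load_real_inputs(config: RunConfig) -> tuple[DWISeries, PhantomTruth]:
    import nibabel as nib

    series = DWISeries.from_nifti(config.dwi_path, config.scheme)
    labels = np.asanyarray(nib.load(str(config.mask_path)).dataobj).astype(int)
    lesions = pd.read_csv(config.labels_path)
    need = {"lesion_id", "class_name"}
    if not need <= set(lesions.columns):
        raise ConfigurationError(f"labels table needs columns {sorted(need)}")
    if "gleason" not in lesions.columns:
        lesions["gleason"] = np.nan
    return series, PhantomTruth(labels=labels, lesions=lesions, voxels=pd.DataFrame())


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return the report bundle (not written).

    Stages: phantom generation (or input loading), joint IVIM-kurtosis map
    fitting plus two-point ADC over the union of the lesion ROIs and the
    simulated observer re-readings (so every summarized voxel is fitted
    exactly once), per-lesion
    histogram features, gated group tests, Spearman vs Gleason score,
    observer-ICC simulation, per-feature ROC, combined logistic models and
    the DeLong model comparison.
    """
    log: list[str] = []
    if config.phantom is not None:
        spec = config.phantom
        if spec.seed != config.seed:
            spec = PhantomSpec(**{**asdict(spec), "seed": config.seed})
        series, truth = generate_phantom(spec, config.scheme, config.classes)
        log.append(
            f"phantom: {len(truth.lesions)} lesions "
            f"({(truth.lesions['class_name'] == 'PCa').sum()} PCa), sigma={spec.sigma}"
        )
    else:
        series, truth = _load_real_inputs(config)
        log.append(f"loaded {config.dwi_path}: {len(truth.lesions)} lesions")

    fit_region = truth.roi_mask.copy()
    observer_masks = None
    if config.icc_enabled:
        observer_masks = _observer_masks(truth, config)
        for variant in observer_masks.values():
            for m in variant.values():
                fit_region |= m
    maps = fit_maps(series, fit_region, config.fit_options)
    n_exc = int((maps.status == 2).sum())
    n_fail = int((maps.status == 3).sum())
    log.append(f"fitting: {int((maps.status == 1).sum())} converged, "
               f"{n_exc} excluded, {n_fail} failed")

    features = _summarize_lesions(maps, truth.labels, truth.lesions, log)
    group_table = _group_comparison(features, config.gate_alpha, log)
    if config.fdr_correction:
        group_table["p_adjusted"] = cs.adjust_pvalues(group_table["p"])
    spearman_table = _spearman_table(features)
    icc_table = None
    if config.icc_enabled:
        icc_table = _icc_table(maps, truth, observer_masks, config, log)
    roc_table, comparison, coefs = _roc_and_models(features, group_table, log)

    return ReportBundle(
        lesion_features=features,
        group_table=group_table,
        icc_table=icc_table,
        spearman_table=spearman_table,
        roc_table=roc_table,
        roc_comparison=comparison,
        model_coefficients=coefs,
        log=log,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
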