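"""End-to-end orchestration: simulate -> outliers -> split -> per-component
preprocessing search -> PLSR -> evaluation -> grading, plus CSV I/O.

All randomness flows from one root seed through named substreams (one per
stage), so e.g. changing the candidate chain list never shifts the
generator stream. The run report carries, per chemical component, both the
raw-spectra baseline model and the best-chain model, mirroring the paired
"raw/pretreatment" presentation of calibration tables.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CHEMICAL_COMPONENTS, VARIABLES, SpectraSet, align_composition
from .outliers import mahalanobis_outliers, pca_decompose, remove_outliers
from .plsr import evaluate, fit_plsr, select_n_latent
from .preprocess import PreprocessChain, default_candidate_chains, select_best_chain
from .split import kennard_stone, n_cal_for_ratio
from .stats_grading import cluster_and_type, grade_samples, grading_summary
from .synthetic_data import (
    SpectraGenConfig,
    build_default_spec,
    generate_spectra,
    sample_composition,
)

#: Units of the composition/sensory variables (sidecar metadata).
UNITS = {
    "starch": "g/100 g",
    "crude_protein": "g/100 g",
    "moisture": "%",
    "crude_fiber": "g/100 g",
    "crude_fat": "g/100 g",
    "length": "mm",
    "width": "mm",
    "height": "mm",
    "hundred_seed_weight": "g",
    "seed_shape": "ordinal 1-4",
    "color": "ordinal 1-4",
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    mix = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Wide CSV: sample_id column, then one column per wavelength (nm)."""
    df = pd.DataFrame(
        spectra.absorbance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[f"{w:g}" for w in spectra.wavelengths],
    )
    df.to_csv(path, float_format="%.17g")


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV; validates ids, cells and wavelength order."""
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
    if dupes.size:
        raise ValueError(f"duplicate sample id: {dupes[0]!r}")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength columns are not strictly increasing")
    body = df.iloc[:, 1:]
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"non-numeric cell at row {row} (id {ids[row]!r}), column {col!r}"
            )
        if converted.isna().any():
            row = int(np.nonzero(converted.isna().to_numpy())[0][0])
            raise ValueError(f"missing value at row {row}, column {col!r}")
    return SpectraSet(wavelengths, body.to_numpy(dtype=float), ids)


def write_composition_csv(comp: pd.DataFrame, path: str | Path) -> None:
    """Composition CSV plus a ``*.units.json`` sidecar with units."""
    path = Path(path)
    comp.to_csv(path, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".units.json")
    units = {c: UNITS.get(c, "") for c in comp.columns}
    sidecar.write_text(json.dumps(units, indent=2, sort_keys=True))


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    return df


# --------------------------------------------------------------------------
# Configuration and report
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a run needs; one root seed, no silent nondeterminism."""

    n_samples: int = 90
    seed: int = 0
    scatter_slope_sd: float = 0.005
    scatter_offset_sd: float = 0.02
    baseline_poly_coeff_sds: tuple[float, float, float] = (0.005, 0.005, 0.005)
    noise_sd: float = 3e-4
    outlier_threshold: float = 0.5
    max_removed: int = 10
    split_ratio: float = 0.75
    n_cal: int | None = None
    cv_folds: int = 10
    max_latent: int = 15
    candidate_chains: list[list[str]] | None = None
    grading: bool = True
    spectra_csv: str | None = None
    composition_csv: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.baseline_poly_coeff_sds, list):
            cfg.baseline_poly_coeff_sds = tuple(cfg.baseline_poly_coeff_sds)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_poly_coeff_sds"] = list(self.baseline_poly_coeff_sds)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComponentResult:
    """Raw-baseline and best-chain models for one chemical component."""

    component: str
    chain: list[str]
    n_latent_raw: int
    n_latent_pre: int
    metrics_raw: dict
    metrics_pre: dict
    failed: bool = False
    error: str | None = None


@dataclass
class RunReport:
    components: dict[str, ComponentResult]
    outlier_ids: list[str]
    calibration_ids: list[str]
    validation_ids: list[str]
    grading_summary: dict
    version: str
    config_hash: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "components": {
                k: {
                    "component": v.component,
                    "chain": v.chain,
                    "n_latent_raw": v.n_latent_raw,
                    "n_latent_pre": v.n_latent_pre,
                    "metrics_raw": v.metrics_raw,
                    "metrics_pre": v.metrics_pre,
                    "failed": v.failed,
                    "error": v.error,
                }
                for k, v in self.components.items()
            },
            "outlier_ids": self.outlier_ids,
            "calibration_ids": self.calibration_ids,
            "validation_ids": self.validation_ids,
            "grading_summary": self.grading_summary,
            "version": self.version,
            "config_hash": self.config_hash,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _simulate_inputs(config: PipelineConfig) -> tuple[SpectraSet, pd.DataFrame]:
    spec = build_default_spec()
    comp = sample_composition(
        spec, config.n_samples, seed=stage_seed(config.seed, "composition")
    )
    gen = SpectraGenConfig(
        scatter_slope_sd=config.scatter_slope_sd,
        scatter_offset_sd=config.scatter_offset_sd,
        baseline_poly_coeff_sds=tuple(config.baseline_poly_coeff_sds),
        noise_sd=config.noise_sd,
        rng_seed=stage_seed(config.seed, "spectra"),
    )
    return generate_spectra(comp, config=gen), comp


def load_or_simulate(config: PipelineConfig) -> tuple[SpectraSet, pd.DataFrame]:
    if (config.spectra_csv is None) != (config.composition_csv is None):
        raise ValueError("provide both spectra_csv and composition_csv, or neither")
    if config.spectra_csv is not None:
        spectra = read_spectra_csv(config.spectra_csv)
        comp = read_composition_csv(config.composition_csv)
        return spectra, align_composition(spectra, comp)
    return _simulate_inputs(config)


def fit_component_models(
    spectra: SpectraSet,
    comp: pd.DataFrame,
    split,
    component: str,
    config: PipelineConfig,
) -> ComponentResult:
    """Raw-baseline and best-chain PLSR models for one component."""
    x = spectra.absorbance
    lam = spectra.wavelengths
    y = comp[component].to_numpy(dtype=float)
    cal, val = split.calibration_idx, split.validation_idx
    x_cal, x_val = x[cal], x[val]
    y_cal, y_val = y[cal], y[val]
    seed = stage_seed(config.seed, f"model:{component}")

    # raw baseline
    nl_raw, secv_raw = select_n_latent(
        x_cal, y_cal, max_latent=config.max_latent, cv_folds=config.cv_folds,
        seed=seed,
    )
    model_raw = fit_plsr(x_cal, y_cal, nl_raw)
    m_raw = evaluate(model_raw, x_cal, y_cal, x_val, y_val, secv=secv_raw[nl_raw - 1])

    # best preprocessing chain, selected on calibration data only
    candidates = (
        [PreprocessChain.from_kinds(k) for k in config.candidate_chains]
        if config.candidate_chains is not None
        else default_candidate_chains()
    )
    best, _ = select_best_chain(
        x_cal, y_cal, lam,
        candidate_chains=candidates,
        n_latent_max=config.max_latent,
        cv_folds=config.cv_folds,
        seed=seed,
    )
    chain = best.copy()
    for step in chain.steps:  # refit stateful steps cleanly on calibration
        step.params.pop("msc_reference", None)
    xp_cal = chain.fit_transform(x_cal, lam)
    xp_val = chain.transform(x_val, lam)
    nl_pre, secv_pre = select_n_latent(
        xp_cal, y_cal, max_latent=config.max_latent, cv_folds=config.cv_folds,
        seed=seed,
    )
    model_pre = fit_plsr(xp_cal, y_cal, nl_pre)
    m_pre = evaluate(
        model_pre, xp_cal, y_cal, xp_val, y_val, secv=secv_pre[nl_pre - 1]
    )

    return ComponentResult(
        component=component,
        chain=chain.kinds,
        n_latent_raw=nl_raw,
        n_latent_pre=nl_pre,
        metrics_raw=m_raw.as_dict(),
        metrics_pre=m_pre.as_dict(),
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and return the full run report."""
    spectra, comp = load_or_simulate(config)

    pca = pca_decompose(spectra)
    report = mahalanobis_outliers(pca, threshold=config.outlier_threshold)
    spectra, comp, removed = remove_outliers(
        spectra, comp, report, max_removed=config.max_removed
    )

    n = spectra.n_samples
    n_cal = config.n_cal if config.n_cal is not None else n_cal_for_ratio(
        n, config.split_ratio
    )
    split = kennard_stone(spectra.absorbance, n_cal, spectra.sample_ids)

    components: dict[str, ComponentResult] = {}
    for comp_name in CHEMICAL_COMPONENTS:
        try:
            components[comp_name] = fit_component_models(
                spectra, comp, split, comp_name, config
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            components[comp_name] = ComponentResult(
                component=comp_name,
                chain=[],
                n_latent_raw=0,
                n_latent_pre=0,
                metrics_raw={},
                metrics_pre={},
                failed=True,
                error=str(exc),
            )

    grading: dict = {}
    if config.grading:
        labels, mapping = cluster_and_type(
            comp, k=3, seed=stage_seed(config.seed, "kmeans")
        )
        classes = labels.map(mapping) if mapping else None
        grades = grade_samples(comp, variety_class=classes)
        grading = grading_summary(grades)

    run = RunReport(
        components=components,
        outlier_ids=removed,
        calibration_ids=split.calibration_ids,
        validation_ids=split.validation_ids,
        grading_summary=grading,
        version=__version__,
        config_hash=config.config_hash(),
        config=config.to_dict(),
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(run.to_json())
        make_table4(run).to_csv(out / "table4.csv", index=False)
        write_spectra_csv(spectra, out / "spectra.csv")
        write_composition_csv(comp, out / "composition.csv")
    return run


def make_table4(report: RunReport) -> pd.DataFrame:
    """Paired raw/pretreated metrics table, one row per component."""
    if not report.components:
        raise ValueError("empty report")
    chain_names = {
        "derivative1": "Derivative (1st)",
        "derivative2": "Derivative (2nd)",
        "detrend": "Detrend",
        "snv": "SNV",
        "msc": "MSC",
        "smoothing": "Smoothing",
        "normalization": "Normalization",
        "baseline": "Baseline",
    }
    rows = []
    for name, res in report.components.items():
        if res.failed:
            rows.append({"Index": name, "Raw/pretreatment method": "failed"})
            continue
        pretty = " + ".join(chain_names.get(k, k) for k in res.chain) or "Raw"

        def pair(key: str, r=res) -> str:
            return f"{r.metrics_raw[key]:.2f}/{r.metrics_pre[key]:.2f}"

        rows.append(
            {
                "Index": name,
                "Raw/pretreatment method": f"Raw/{pretty}",
                "R2c": pair("r2_c"),
                "RMSEC": pair("rmsec"),
                "RPDC": pair("rpd_c"),
                "R2p": pair("r2_p"),
                "RMSEP": pair("rmsep"),
                "RPDP": pair("rpd_p"),
            }
        )
    return pd.DataFrame(rows)
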