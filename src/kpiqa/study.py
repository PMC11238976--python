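"""Orchestration of the validation experiments and correlation analysis.

Two experiments mirror how a keypoint-feature quality index is validated
against the conventional full-reference metrics:

validity
    Degrade the reference by dose-dependent quantum noise (a 10-level
    CTDI_vol series) and by Gaussian blur (kernel sizes 3..21), and test the
    Pearson correlation of the index against SSIM (the external criterion),
    with PSNR included for comparison.

robustness
    Apply translations, rotations and scalings — operations that do not
    change intrinsic image quality — and verify that the index stays stable
    while SSIM and PSNR degrade.

All randomness (reference noise, per-condition noise) derives from a single
seed, so a study run is fully reproducible and its reports byte-identical
across runs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import BACKENDS, BackendParams, default_params, detect_and_describe
from .image_io import BRAIN_WINDOW, GrayImage, WindowSpec, to_eight_bit
from .matching import brute_force_match, proposed_index
from .phantom import (
    PAPER_CTDI_SERIES,
    REFERENCE_CTDI,
    DoseNoiseSpec,
    simulate_dose_noise,
)
from .reference_metrics import SSIMParams, psnr, ssim
from .transforms import (
    PAPER_ENLARGEMENT_FACTORS,
    PAPER_REDUCTION_FACTORS,
    AffineSpec,
    BlurSpec,
    apply_affine,
    blur_series,
    gaussian_blur,
    rotation_series,
    scale_series,
    translation_series,
)

__all__ = [
    "BackendRecord",
    "ConditionRecord",
    "CorrelationSummary",
    "StudyResult",
    "pearson_test",
    "run_validity_study",
    "run_robustness_study",
    "write_report",
    "coefficient_of_variation",
    "ALPHA",
]

logger = logging.getLogger("kpiqa")

#: Significance level of the Pearson correlation tests.
ALPHA = 0.05


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    The p-value comes from the exact null transform
    t = r * sqrt((n - 2) / (1 - r^2)) referred to Student's t with n - 2
    degrees of freedom.  Requires n >= 3 and both series non-constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt((xd ** 2).sum())
    sy = np.sqrt((yd ** 2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation is undefined for a constant series")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


@dataclass
class BackendRecord:
    """Per-backend measurements for one degradation condition."""

    keypoints_ref: int
    keypoints_tgt: int
    n_matches: int
    pi: float | None  # None when no correspondences exist (failed condition)


@dataclass
class ConditionRecord:
    """One degradation condition: its parameter, SSIM/PSNR and per-backend PI."""

    series: str
    label: str
    parameter: float
    ssim: float
    psnr: float
    backends: dict[str, BackendRecord] = field(default_factory=dict)


@dataclass
class CorrelationSummary:
    """Pearson correlation of one metric against SSIM over one series."""

    series: str
    backend: str  # backend id, or "psnr" for the PSNR-vs-SSIM row
    metric: str  # "pi" or "psnr"
    n: int
    r: float
    p: float
    significant: bool


@dataclass
class StudyResult:
    """Records, correlation summaries, and the full parameter provenance."""

    kind: str  # "validity" | "robustness"
    records: list[ConditionRecord]
    correlations: list[CorrelationSummary]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "records": [asdict(r) for r in self.records],
            "correlations": [asdict(c) for c in self.correlations],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyResult":
        records = [
            ConditionRecord(
                series=r["series"], label=r["label"], parameter=r["parameter"],
                ssim=r["ssim"], psnr=r["psnr"],
                backends={b: BackendRecord(**br) for b, br in r["backends"].items()},
            )
            for r in d["records"]
        ]
        corrs = [CorrelationSummary(**c) for c in d["correlations"]]
        return cls(kind=d["kind"], records=records, correlations=corrs,
                   provenance=d["provenance"])

    def series_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.series not in seen:
                seen.append(r.series)
        return seen


def coefficient_of_variation(values) -> float:
    """Sample std over mean; 0 for a perfectly constant (or all-zero) series."""
    v = np.asarray(values, dtype=np.float64)
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    mean = float(v.mean())
    if sd == 0.0:
        return 0.0
    if mean == 0.0:
        return float("inf")
    return sd / abs(mean)


# ---------------------------------------------------------------------------
# study construction
# ---------------------------------------------------------------------------

def _make_reference(image: GrayImage, window: WindowSpec, sigma_at_ref: float,
                    ref_ctdi: float, seed: int) -> GrayImage:
    """8-bit reference: windowed reference-dose acquisition of the clean scene.

    An 8-bit input is taken as the reference directly; a 16-bit (HU) input is
    degraded with reference-dose noise and windowed, emulating that even the
    best acquisition carries quantum noise.
    """
    if image.bit_depth == 8:
        return image
    spec = DoseNoiseSpec(ctdi=ref_ctdi, ref_ctdi=ref_ctdi,
                         sigma_at_ref=sigma_at_ref, seed=seed)
    return to_eight_bit(simulate_dose_noise(image, spec), window)


def _backend_param_map(backends, backend_params) -> dict[str, BackendParams]:
    out = {}
    for b in backends:
        bid = b.lower()
        if backend_params and bid in backend_params:
            out[bid] = backend_params[bid]
        else:
            out[bid] = default_params(bid)
    return out


def _measure_condition(series: str, label: str, parameter: float,
                       ref_img: GrayImage, tgt_img: GrayImage,
                       ref_features: dict, params_map: dict,
                       ssim_params: SSIMParams) -> ConditionRecord:
    rec = ConditionRecord(
        series=series, label=label, parameter=parameter,
        ssim=ssim(ref_img, tgt_img, ssim_params),
        psnr=psnr(ref_img, tgt_img, ssim_params.data_range),
    )
    for bid, params in params_map.items():
        kp_ref, d_ref = ref_features[bid]
        kp_tgt, d_tgt = detect_and_describe(tgt_img, params)
        matches = brute_force_match(d_ref, d_tgt)
        if matches.n == 0:
            logger.warning("condition %s/%s: no matches under backend %s; "
                           "excluded from correlation", series, label, bid)
            pi = None
        else:
            pi = proposed_index(matches).value
        rec.backends[bid] = BackendRecord(
            keypoints_ref=len(kp_ref), keypoints_tgt=len(kp_tgt),
            n_matches=matches.n, pi=pi,
        )
    return rec


def _correlate(records: list[ConditionRecord], backends) -> list[CorrelationSummary]:
    """PI-vs-SSIM per backend and PSNR-vs-SSIM, per series."""
    out: list[CorrelationSummary] = []
    series_names: list[str] = []
    for r in records:
        if r.series not in series_names:
            series_names.append(r.series)
    for series in series_names:
        recs = [r for r in records if r.series == series]
        for bid in backends:
            ok = [r for r in recs if r.backends[bid].pi is not None]
            if len(ok) < 3:
                logger.warning("series %s backend %s: fewer than 3 usable "
                               "conditions; correlation skipped", series, bid)
                continue
            try:
                r_val, p_val = pearson_test([r.ssim for r in ok],
                                            [r.backends[bid].pi for r in ok])
            except ValueError:
                logger.warning("series %s backend %s: metric is constant across "
                               "conditions; correlation undefined (maximally "
                               "stable), skipped", series, bid)
                continue
            out.append(CorrelationSummary(series=series, backend=bid, metric="pi",
                                          n=len(ok), r=r_val, p=p_val,
                                          significant=p_val < ALPHA))
        finite = [r for r in recs if np.isfinite(r.psnr)]
        if len(finite) < 3:
            logger.warning("series %s: fewer than 3 finite-PSNR conditions; "
                           "PSNR correlation skipped", series)
            continue
        try:
            r_val, p_val = pearson_test([r.ssim for r in finite],
                                        [r.psnr for r in finite])
        except ValueError:
            logger.warning("series %s: degenerate PSNR/SSIM series; "
                           "correlation skipped", series)
            continue
        out.append(CorrelationSummary(series=series, backend="psnr", metric="psnr",
                                      n=len(finite), r=r_val, p=p_val,
                                      significant=p_val < ALPHA))
    return out


def _provenance(kind, backends, params_map, ssim_params, window, seed,
                sigma_at_ref, ref_ctdi, extra) -> dict:
    prov = {
        "kind": kind,
        "backends": list(backends),
        "backend_params": {b: asdict(p) for b, p in params_map.items()},
        "ssim_params": asdict(ssim_params),
        "window": {"center": window.center, "width": window.width},
        "seed": seed,
        "sigma_at_ref": sigma_at_ref,
        "ref_ctdi": ref_ctdi,
    }
    prov.update(extra)
    return prov


def run_validity_study(
    image: GrayImage,
    noise_series=PAPER_CTDI_SERIES,
    blur_kernels=None,
    backends=BACKENDS,
    backend_params: dict[str, BackendParams] | None = None,
    ssim_params: SSIMParams | None = None,
    window: WindowSpec = BRAIN_WINDOW,
    sigma_at_ref: float = 3.0,
    ref_ctdi: float = REFERENCE_CTDI,
    seed: int = 0,
) -> StudyResult:
    """Noise and blur series versus SSIM (the validity experiment).

    ``image`` is the clean scene: a 16-bit HU image is acquired at the
    reference dose (noise + windowing) to form the reference, and noise
    targets are fresh acquisitions of the same scene at each CTDI in
    ``noise_series``; blur targets blur the reference itself.  ``noise_series``
    accepts CTDI floats or ready-made :class:`DoseNoiseSpec` entries.
    """
    ssim_params = ssim_params or SSIMParams()
    params_map = _backend_param_map(backends, backend_params)
    seeds = np.random.default_rng(seed).integers(2 ** 31, size=1 + len(noise_series))
    ref_img = _make_reference(image, window, sigma_at_ref, ref_ctdi, int(seeds[0]))
    ref_features = {b: detect_and_describe(ref_img, p) for b, p in params_map.items()}

    records: list[ConditionRecord] = []
    for i, entry in enumerate(noise_series):
        if isinstance(entry, DoseNoiseSpec):
            spec = entry
        else:
            spec = DoseNoiseSpec(ctdi=float(entry), ref_ctdi=ref_ctdi,
                                 sigma_at_ref=sigma_at_ref, seed=int(seeds[1 + i]))
        tgt = to_eight_bit(simulate_dose_noise(image, spec), window) \
            if image.bit_depth != 8 else simulate_dose_noise(image, spec)
        records.append(_measure_condition(
            "noise", f"ctdi_{spec.ctdi:g}mGy", spec.ctdi, ref_img, tgt,
            ref_features, params_map, ssim_params))

    for spec in (blur_series() if blur_kernels is None
                 else [k if isinstance(k, BlurSpec) else BlurSpec(int(k))
                       for k in blur_kernels]):
        tgt = gaussian_blur(ref_img, spec)
        records.append(_measure_condition(
            "blur", f"kernel_{spec.kernel_size}", float(spec.kernel_size),
            ref_img, tgt, ref_features, params_map, ssim_params))

    correlations = _correlate(records, list(params_map))
    prov = _provenance("validity", list(params_map), params_map, ssim_params,
                       window, seed, sigma_at_ref, ref_ctdi, {
                           "noise_ctdi": [float(getattr(e, "ctdi", e))
                                          for e in noise_series],
                           "blur_kernels": [s.kernel_size for s in (
                               blur_series() if blur_kernels is None else
                               [k if isinstance(k, BlurSpec) else BlurSpec(int(k))
                                for k in blur_kernels])],
                       })
    return StudyResult("validity", records, correlations, prov)


def default_affine_series() -> dict[str, list[AffineSpec]]:
    return {
        "translation": translation_series(),
        "rotation": rotation_series(),
        "reduction": scale_series(PAPER_REDUCTION_FACTORS),
        "enlargement": scale_series(PAPER_ENLARGEMENT_FACTORS),
    }


def _affine_parameter(spec: AffineSpec) -> float:
    if spec.kind == "translate":
        return float(np.hypot(spec.dx, spec.dy))
    if spec.kind == "rotate":
        return float(spec.angle)
    return float(spec.factor)


def run_robustness_study(
    image: GrayImage,
    affine_series: dict[str, list[AffineSpec]] | None = None,
    backends=BACKENDS,
    backend_params: dict[str, BackendParams] | None = None,
    ssim_params: SSIMParams | None = None,
    window: WindowSpec = BRAIN_WINDOW,
    sigma_at_ref: float = 3.0,
    ref_ctdi: float = REFERENCE_CTDI,
    seed: int = 0,
    independent_target: bool = True,
) -> StudyResult:
    """Affine series (quality-preserving transforms) versus SSIM.

    The same reference construction as the validity study.  By default the
    transformed target is a second, independently noised reference-dose
    acquisition of the same scene — two scans at the same dose share the
    signal but not the quantum noise — so the index sits at its same-dose
    operating level and any change across the series reflects the transform,
    not image quality.  With ``independent_target=False`` (or an 8-bit
    input, which carries no noise model) the reference image itself is
    transformed, in which case identity parameters give PI = 0 exactly.
    """
    affine_series = affine_series or default_affine_series()
    ssim_params = ssim_params or SSIMParams()
    params_map = _backend_param_map(backends, backend_params)
    seeds = np.random.default_rng(seed).integers(2 ** 31, size=2)
    ref_img = _make_reference(image, window, sigma_at_ref, ref_ctdi, int(seeds[0]))
    if independent_target and image.bit_depth != 8:
        tgt_base = _make_reference(image, window, sigma_at_ref, ref_ctdi,
                                   int(seeds[1]))
    else:
        tgt_base = ref_img
    ref_features = {b: detect_and_describe(ref_img, p) for b, p in params_map.items()}

    records: list[ConditionRecord] = []
    for series, specs in affine_series.items():
        for spec in specs:
            tgt = apply_affine(tgt_base, spec)
            records.append(_measure_condition(
                series, spec.label, _affine_parameter(spec), ref_img, tgt,
                ref_features, params_map, ssim_params))

    correlations = _correlate(records, list(params_map))
    prov = _provenance("robustness", list(params_map), params_map, ssim_params,
                       window, seed, sigma_at_ref, ref_ctdi, {
                           "independent_target": bool(independent_target
                                                      and image.bit_depth != 8),
                           "affine_series": {
                               name: [asdict(s) for s in specs]
                               for name, specs in affine_series.items()},
                       })
    return StudyResult("robustness", records, correlations, prov)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _conditions_frame(result: StudyResult) -> pd.DataFrame:
    backends = result.provenance.get("backends", [])
    rows = []
    for rec in result.records:
        row: dict = {"series": rec.series, "label": rec.label,
                     "parameter": rec.parameter, "ssim": rec.ssim,
                     "psnr": rec.psnr}
        for b in backends:
            br = rec.backends[b]
            row[f"{b}_keypoints"] = br.keypoints_tgt
            row[f"{b}_matchings"] = br.n_matches
            row[f"{b}_pi"] = br.pi
        rows.append(row)
    return pd.DataFrame(rows)


def _correlations_frame(result: StudyResult) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in result.correlations])


def _scatter_plots(result: StudyResult, out_dir: str) -> list[str]:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    backends = result.provenance.get("backends", [])
    written = []
    for series in result.series_names():
        recs = [r for r in result.records if r.series == series]
        fig, ax = plt.subplots(figsize=(5.5, 4.2))
        ax2 = ax.twinx()
        for b in backends:
            pts = [(r.ssim, r.backends[b].pi) for r in recs
                   if r.backends[b].pi is not None]
            if pts:
                xs, ys = zip(*pts)
                ax.plot(xs, ys, "o", label=b)
        finite = [(r.ssim, r.psnr) for r in recs if np.isfinite(r.psnr)]
        if finite:
            xs, ys = zip(*finite)
            ax2.plot(xs, ys, "x--", color="gray", label="psnr")
        ax.set_xlabel("SSIM")
        ax.set_ylabel("quality index (mean Hamming distance, bits)")
        ax2.set_ylabel("PSNR [dB]")
        ax.set_title(f"{result.kind}: {series} series")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        path = os.path.join(out_dir, f"scatter_{result.kind}_{series}.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def write_report(result: StudyResult, out_dir: str, plots: bool = True) -> dict:
    """Write CSV tables, a JSON archive, and scatter plots into ``out_dir``.

    The CSV/JSON outputs are byte-deterministic for a fixed study result.
    Returns the paths written, keyed by artifact name.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "conditions_csv": os.path.join(out_dir, f"conditions_{result.kind}.csv"),
        "correlations_csv": os.path.join(out_dir, f"correlations_{result.kind}.csv"),
        "json": os.path.join(out_dir, f"result_{result.kind}.json"),
    }
    _conditions_frame(result).to_csv(paths["conditions_csv"], index=False)
    _correlations_frame(result).to_csv(paths["correlations_csv"], index=False)
    with open(paths["json"], "w") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if plots:
        paths["plots"] = _scatter_plots(result, out_dir)
    return paths


def read_report(path: str) -> StudyResult:
    """Re-load a study result from its JSON archive."""
    with open(path) as fh:
        return StudyResult.from_dict(json.load(fh))
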