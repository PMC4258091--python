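"""Genome scan: per-window likelihood-ratio tests of regional variance.

Each window is tested by comparing the full model (polygenic kernel plus the
window's regional kernel) against the null (polygenic kernel only). Because
the regional variance sits on the parameter boundary under the null, the LRT
is referred to the half-half mixture of a point mass at zero and chi-square
with one degree of freedom. Two polygenic modes are supported:

``whole_G``
    One genome-wide kernel, so a single null fit is shared by every window.

``loco_G``
    One 'n-1' kernel per chromosome, always excluding the chromosome being
    interrogated; each window's full model pairs its chromosome's LOCO kernel
    with the regional kernel. This keeps nested models valid and stops long
    within-family LD from letting the polygenic term swallow a regional QTL.

Multiple testing: with overlapping windows (step = half the window size) only
half of the tested windows are counted in the Bonferroni correction, so the
genome-wide threshold solves ``mixture_p = alpha / ceil(n_windows / 2)`` and
the suggestive threshold (one false positive per scan) solves
``mixture_p = 1 / n_windows``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .kernels import (Kernel, Window, block_diagonalize, compute_grm,
                      loco_kernel, make_windows, regional_kernel)
from .panel import GenotypePanel
from .reml import KernelREML, REMLFit

MODES = ("whole_G", "loco_G")


# ---------------------------------------------------------------------------
# mixture distribution arithmetic
# ---------------------------------------------------------------------------

def mixture_pvalue(lrt):
    """Upper-tail probability of the half-half mixture of chi2_0 and chi2_1.

    ``p = 0.5 * Pr(chi2_1 >= lrt)`` for positive statistics and 1 at zero.
    """
    arr = np.asarray(lrt, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LRT must be non-negative (clamp upstream)")
    p = np.where(arr > 0, 0.5 * chi2.sf(arr, df=1), 1.0)
    return float(p) if np.isscalar(lrt) or arr.ndim == 0 else p


def _invert_mixture(target_p: float) -> float:
    """LRT value whose mixture p equals ``target_p`` (monotone root-finding)."""
    if target_p >= 0.5:
        warnings.warn("target mixture p >= 0.5: threshold degenerates to 0")
        return 0.0
    lo, hi = 1e-12, 10.0
    while mixture_pvalue(hi) > target_p:
        hi *= 2.0
    return float(brentq(lambda t: mixture_pvalue(t) - target_p, lo, hi,
                        xtol=1e-10, rtol=1e-12))


def lrt_thresholds(n_windows: int, alpha: float = 0.05) -> tuple[float, float]:
    """(genome-wide, suggestive) LRT thresholds for a scan of ``n_windows``.

    Genome-wide: Bonferroni over half the (overlapping) windows,
    ``mixture_p = alpha / ceil(n_windows / 2)``. Suggestive: one false
    positive per scan, ``mixture_p = 1 / n_windows``.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    divisor = -(-n_windows // 2)  # ceil
    genomewide = _invert_mixture(alpha / divisor)
    suggestive = _invert_mixture(1.0 / n_windows)
    return genomewide, suggestive


# ---------------------------------------------------------------------------
# scan configuration / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanConfig:
    mode: str = "whole_G"
    window_size: int = 100
    step: int = 50
    alpha: float = 0.05
    freq_scope: str = "per_population"
    block_diagonal: bool = True
    stabilize: float = 1e-8
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ScanResult:
    results: pd.DataFrame
    mode: str
    n_windows: int
    genomewide_threshold: float
    suggestive_threshold: float
    null_logliks: dict           # chrom -> loglik ("all" in whole_G mode)
    null_fits: dict              # chrom -> REMLFit
    n_null_fits: int
    n_nonconverged: int


RESULT_COLUMNS = ["chrom", "window", "first_snp", "last_snp", "start_bp",
                  "end_bp", "n_snps", "lrt", "p", "neg_log10_p", "sigma2_g",
                  "sigma2_r", "sigma2_e", "h2", "h2_r", "converged",
                  "significance"]


class RegionalHeritabilityScan(BaseEstimator):
    """Sliding-window regional-variance scan as a fit-shaped estimator.

    ``fit(panel, y)`` runs the scan of ``y`` (one standardized animal effect
    per panel animal, in panel order) and exposes the per-window table as
    ``results_`` plus a :class:`ScanResult` as ``scan_``.
    """

    def __init__(self, mode: str = "whole_G", window_size: int = 100,
                 step: int = 50, alpha: float = 0.05,
                 freq_scope: str = "per_population",
                 block_diagonal: bool = True, stabilize: float = 1e-8,
                 max_iter: int = 200, tol: float = 1e-6,
                 population_fixed_effect: bool = True):
        self.mode = mode
        self.window_size = window_size
        self.step = step
        self.alpha = alpha
        self.freq_scope = freq_scope
        self.block_diagonal = block_diagonal
        self.stabilize = stabilize
        self.max_iter = max_iter
        self.tol = tol
        self.population_fixed_effect = population_fixed_effect

    # -- helpers -----------------------------------------------------------
    def _fixed_design(self, panel: GenotypePanel) -> np.ndarray:
        n = panel.n_animals
        X = [np.ones(n)]
        if self.population_fixed_effect:
            pops = pd.unique(panel.populations)
            for pop in pops[1:]:
                X.append((panel.populations == pop).astype(float))
        return np.column_stack(X)

    def _polygenic_kernel(self, panel: GenotypePanel, chrom=None) -> Kernel:
        if chrom is None:
            k = compute_grm(panel, freq_scope=self.freq_scope, provenance="whole")
        else:
            k = loco_kernel(panel, chrom, freq_scope=self.freq_scope)
        if self.block_diagonal and not k.block_diagonal:
            k = block_diagonalize(k, panel.populations)
        return k

    def _reml(self, kernels, labels, X, y, init=None) -> REMLFit:
        est = KernelREML(kernels=kernels, labels=labels, max_iter=self.max_iter,
                         tol=self.tol, stabilize=self.stabilize, init=init)
        est.fit(X, y)
        return est.fit_

    @staticmethod
    def _warm_start(null: REMLFit) -> list[float]:
        # deterministic: null components plus a small positive regional seed
        sp = null.sigma2_p
        return [null.sigma2_g, 0.02 * sp, null.sigma2_e]

    # -- main entry ----------------------------------------------------------
    def fit(self, panel: GenotypePanel, y):
        cfg = ScanConfig(mode=self.mode, window_size=self.window_size,
                         step=self.step, alpha=self.alpha,
                         freq_scope=self.freq_scope,
                         block_diagonal=self.block_diagonal,
                         stabilize=self.stabilize, max_iter=self.max_iter,
                         tol=self.tol)
        if isinstance(y, pd.Series):
            y = y.reindex(list(panel.animal_ids)).to_numpy()
        y = np.asarray(y, dtype=float)
        if len(y) != panel.n_animals:
            raise ValueError("trait vector must align with the panel animals")
        if np.isnan(y).any():
            raise ValueError("trait vector contains missing values")
        X = self._fixed_design(panel)

        windows = make_windows(panel.snps, cfg.window_size, cfg.step)
        gw_t, sugg_t = lrt_thresholds(len(windows), cfg.alpha)

        poly_cache: dict = {}
        null_fits: dict = {}
        if cfg.mode == "whole_G":
            poly_cache["all"] = self._polygenic_kernel(panel)
            null_fits["all"] = self._reml([poly_cache["all"]], ["genomic"], X, y)
        else:
            for chrom in panel.chromosomes:
                poly_cache[chrom] = self._polygenic_kernel(panel, chrom)
                null_fits[chrom] = self._reml([poly_cache[chrom]],
                                              ["genomic"], X, y)
        n_null_fits = len(null_fits)

        rows = []
        n_noncv = 0
        for w in windows:
            key = "all" if cfg.mode == "whole_G" else w.chrom
            k_poly = poly_cache[key]
            k_reg = regional_kernel(panel, w, freq_scope=cfg.freq_scope)
            if cfg.block_diagonal and not k_reg.block_diagonal:
                k_reg = block_diagonalize(k_reg, panel.populations)
            null = null_fits[key]
            full = self._reml([k_poly, k_reg], ["genomic", "regional"], X, y,
                              init=self._warm_start(null))
            lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
            p = mixture_pvalue(lrt)
            conv = full.converged and null.converged
            if not conv:
                n_noncv += 1
                sig = "none"
            elif lrt >= gw_t:
                sig = "genomewide"
            elif lrt >= sugg_t:
                sig = "suggestive"
            else:
                sig = "none"
            rows.append((w.chrom, w.index, w.first_snp, w.last_snp, w.start_bp,
                         w.end_bp, w.n_snps, lrt, p, -np.log10(p),
                         full.sigma2_g, full.sigma2_r, full.sigma2_e,
                         full.h2, full.h2_regional, conv, sig))

        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        self.windows_ = windows
        self.results_ = results
        self.genomewide_threshold_ = gw_t
        self.suggestive_threshold_ = sugg_t
        self.scan_ = ScanResult(
            results=results, mode=cfg.mode, n_windows=len(windows),
            genomewide_threshold=gw_t, suggestive_threshold=sugg_t,
            null_logliks={k: f.loglik for k, f in null_fits.items()},
            null_fits=null_fits, n_null_fits=n_null_fits,
            n_nonconverged=n_noncv)
        return self


def scan(panel: GenotypePanel, y, config: ScanConfig | None = None,
         **kwargs) -> ScanResult:
    """Run a scan with a :class:`ScanConfig` (functional wrapper)."""
    cfg = config or ScanConfig(**kwargs)
    est = RegionalHeritabilityScan(mode=cfg.mode, window_size=cfg.window_size,
                                   step=cfg.step, alpha=cfg.alpha,
                                   freq_scope=cfg.freq_scope,
                                   block_diagonal=cfg.block_diagonal,
                                   stabilize=cfg.stabilize,
                                   max_iter=cfg.max_iter, tol=cfg.tol)
    est.fit(panel, y)
    return est.scan_


def window_lrt(panel: GenotypePanel, y, window: Window, mode: str = "whole_G",
               **kwargs) -> dict:
    """LRT for a single window without scanning the whole genome.

    Returns a dict with the full and null fits and the clamped LRT; useful for
    targeted checks such as comparing whole-G against LOCO behaviour at a
    planted QTL.
    """
    est = RegionalHeritabilityScan(mode=mode, **kwargs)
    if isinstance(y, pd.Series):
        y = y.reindex(list(panel.animal_ids)).to_numpy()
    y = np.asarray(y, dtype=float)
    X = est._fixed_design(panel)
    k_poly = est._polygenic_kernel(
        panel, None if mode == "whole_G" else window.chrom)
    k_reg = regional_kernel(panel, window, freq_scope=est.freq_scope)
    if est.block_diagonal and not k_reg.block_diagonal:
        k_reg = block_diagonalize(k_reg, panel.populations)
    null = est._reml([k_poly], ["genomic"], X, y)
    full = est._reml([k_poly, k_reg], ["genomic", "regional"], X, y)
    return {"lrt": max(0.0, 2.0 * (full.loglik - null.loglik)),
            "full": full, "null": null}


def summarize(result: ScanResult, category: str = "suggestive") -> pd.DataFrame:
    """Significant-window table: chromosome, window, flanking SNPs and
    positions, LRT and regional heritability.

    ``category="genomewide"`` keeps genome-wide hits only; ``"suggestive"``
    keeps suggestive-or-better.
    """
    if category not in ("suggestive", "genomewide"):
        raise ValueError("category must be 'suggestive' or 'genomewide'")
    keep = (["genomewide"] if category == "genomewide"
            else ["genomewide", "suggestive"])
    sub = result.results[result.results["significance"].isin(keep)]
    return sub[["chrom", "window", "first_snp", "start_bp", "last_snp",
                "end_bp", "lrt", "h2_r", "significance"]].reset_index(drop=True)


def plot_lrt_profile(result: ScanResult, path, chrom=None) -> None:
    """LRT against window midpoint, with the two thresholds drawn."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.results
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    fig, ax = plt.subplots(figsize=(9, 3.2))
    if chrom is None:
        xticks, xlabels, offset = [], [], 0
        for c, sub in df.groupby("chrom", sort=False):
            x = offset + np.arange(len(sub))
            ax.plot(x, sub["lrt"], marker=".", lw=0.8)
            xticks.append(offset + len(sub) / 2)
            xlabels.append(str(c))
            offset += len(sub)
        ax.set_xticks(xticks, xlabels)
        ax.set_xlabel("chromosome")
    else:
        mid = (df["start_bp"] + df["end_bp"]) / 2e6
        ax.plot(mid, df["lrt"], marker=".", lw=0.8)
        ax.set_xlabel(f"position on {chrom} (Mb)")
    ax.axhline(result.genomewide_threshold, color="k", ls="-", lw=0.8)
    ax.axhline(result.suggestive_threshold, color="k", ls="--", lw=0.8)
    ax.set_ylabel("LRT")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
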