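"""Per-strand methylated-fraction estimation from SMRT kinetics.

The population-average inter-pulse-duration (IPD) ratio at a motif adenine
is modelled as a two-state linear mixture

    r = f * r_full + (1 - f) * 1

where ``f`` is the fraction of chromosomes in the population methylated at
that strand position, ``r_full`` the ratio of a site methylated in every
chromosome (calibrated on a constitutively methylating strain) and 1 the
ratio of unmethylated DNA by construction. Inverting the mixture gives the
estimator ``f = (r - 1) / (r_full - 1)``, clipped to [0, 1]. A strand
adenine whose mean ratio falls below a threshold ``tau`` (default 2.4, i.e.
fully methylated in ~20% of chromosomes) is called under-methylated; a
motif is under-methylated when both strands are, and asymmetrically
methylated when exactly one is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeRecord, circular_distance

KINETICS_COLUMNS = ["contig", "position", "strand", "ipd_ratio", "coverage"]

STRAND_LABELS = ("methylated", "under_methylated", "no_data")
SITE_LABELS = ("full", "asymmetric", "under_methylated", "no_data")


@dataclass(frozen=True)
class CalibrationModel:
    """Two-state mixing calibration.

    r_full is the population-average IPD ratio of an adenine methylated in
    all chromosomes; r_hemi = (r_full + 1) / 2 follows from the mixture;
    unmethylated DNA has ratio 1 by definition of the IPD ratio.
    """

    r_full: float
    tau: float = 2.4
    r_unmeth: float = 1.0

    def __post_init__(self):
        if not self.r_full > self.r_unmeth:
            raise ValueError(
                f"degenerate calibration: r_full={self.r_full:.4g} must exceed "
                f"r_unmeth={self.r_unmeth:.4g} (r_full > r_hemi > r_unmeth)"
            )
        if not (self.r_unmeth < self.tau < self.r_full):
            raise ValueError(
                f"threshold tau={self.tau:.4g} outside ({self.r_unmeth:.4g}, {self.r_full:.4g})"
            )

    @property
    def r_hemi(self) -> float:
        return (self.r_full + self.r_unmeth) / 2


def motif_adenines(sites, length: int | None = None, circular: bool = True) -> pd.DataFrame:
    """Forward coordinates of the two methylatable adenines of each GANTC.

    For a motif starting at 0-based ``s``: the forward-strand adenine sits
    at ``s + 1`` and the reverse-strand adenine (the T partner on the
    forward strand) at ``s + 3``; positions wrap on circular contigs.
    """
    sites = np.asarray(sites, dtype=int)
    plus = sites + 1
    minus = sites + 3
    if circular:
        if length is None:
            raise ValueError("length required for circular coordinates")
        plus %= length
        minus %= length
    return pd.DataFrame({"site": sites, "plus_pos": plus, "minus_pos": minus})


def calibrate(
    reference_obs: pd.DataFrame,
    min_coverage: int = 5,
    tau: float = 2.4,
    trim: float = 0.0,
) -> CalibrationModel:
    """Estimate r_full from a constitutively methylated reference sample.

    The calibration statistic is the plain mean of the per-adenine IPD
    ratios with coverage >= min_coverage (``trim`` > 0 switches to a
    symmetric trimmed mean for robustness against outlier adenines).
    """
    ok = reference_obs[reference_obs["coverage"] >= min_coverage]
    if ok.empty:
        raise ValueError(
            f"no reference observations with coverage >= {min_coverage}"
        )
    ratios = ok["ipd_ratio"].to_numpy(float)
    r_full = float(stats.trim_mean(ratios, trim)) if trim > 0 else float(ratios.mean())
    return CalibrationModel(r_full=r_full, tau=tau)


def methylated_fraction(mean_ratio, model: CalibrationModel, clip: bool = True):
    """Invert the mixture: fraction of chromosomes methylated on a strand."""
    f = (np.asarray(mean_ratio, dtype=float) - model.r_unmeth) / (model.r_full - model.r_unmeth)
    if clip:
        f = np.clip(f, 0.0, 1.0)
    return f if f.ndim else float(f)


def hemi_equivalent_fraction(mean_ratio, model: CalibrationModel):
    """Fraction of chromosomes hemi-methylated that would yield this ratio.

    A ratio r is produced either by a fraction f of fully-on-this-strand
    methylated chromosomes or, equivalently, by 2f hemi-methylated ones.
    """
    f = (np.asarray(mean_ratio, dtype=float) - model.r_unmeth) / (model.r_hemi - model.r_unmeth)
    f = np.clip(f, 0.0, 1.0)
    return f if f.ndim else float(f)


def call_strands(
    observations: pd.DataFrame,
    model: CalibrationModel,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Per strand-adenine mean ratio, methylated fraction and label.

    Multiple rows at the same (contig, position, strand) are combined by a
    coverage-weighted mean. Label is ``under_methylated`` iff the mean
    ratio is strictly below ``model.tau`` (the threshold side is a
    convention; it is configurable through ``tau`` itself), ``no_data``
    when total coverage is below ``min_coverage``.
    """
    obs = observations.copy()
    obs["_w"] = obs["ipd_ratio"] * obs["coverage"]
    g = obs.groupby(["contig", "position", "strand"], sort=True).agg(
        coverage=("coverage", "sum"), _w=("_w", "sum"), _n=("ipd_ratio", "size"),
        _plain=("ipd_ratio", "mean"),
    )
    with np.errstate(invalid="ignore"):
        mean_ratio = np.where(g["coverage"] > 0, g["_w"] / g["coverage"], g["_plain"])
    out = g.reset_index()[["contig", "position", "strand", "coverage"]]
    out["mean_ratio"] = mean_ratio
    out["f_raw"] = methylated_fraction(out["mean_ratio"], model, clip=False)
    out["f_meth"] = np.clip(out["f_raw"], 0.0, 1.0)
    out["label"] = np.where(out["mean_ratio"] < model.tau, "under_methylated", "methylated")
    no_data = out["coverage"] < min_coverage
    out.loc[no_data, "label"] = "no_data"
    out.loc[no_data, ["f_meth", "f_raw"]] = np.nan
    return out


def call_sites(
    sites,
    strand_calls: pd.DataFrame,
    chrom_length: int,
    circular: bool = True,
    site_mean: bool = False,
    model: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Pair the two strand calls of each motif and label the site.

    site_label is ``under_methylated`` iff both strands are under,
    ``asymmetric`` iff exactly one is, ``full`` when both are methylated
    and ``no_data`` when either strand lacks data. With ``site_mean=True``
    the two strand mean ratios are averaged and thresholded jointly
    (no asymmetric class in that mode; requires ``model``).
    """
    ad = motif_adenines(sites, length=chrom_length, circular=circular)
    by_key = strand_calls.set_index(["position", "strand"])

    def _lookup(pos, strand, col):
        try:
            return by_key.at[(pos, strand), col]
        except KeyError:
            return np.nan

    rows = []
    for site, plus_pos, minus_pos in ad.itertuples(index=False):
        row = {"site": site, "plus_pos": plus_pos, "minus_pos": minus_pos}
        for name, pos, strand in (("plus", plus_pos, "+"), ("minus", minus_pos, "-")):
            row[f"{name}_ratio"] = _lookup(pos, strand, "mean_ratio")
            row[f"{name}_f"] = _lookup(pos, strand, "f_meth")
            label = _lookup(pos, strand, "label")
            row[f"{name}_label"] = label if isinstance(label, str) else "no_data"
        rows.append(row)
    calls = pd.DataFrame(rows)

    if site_mean:
        if model is None:
            raise ValueError("site_mean mode requires the calibration model")
        m = calls[["plus_ratio", "minus_ratio"]].mean(axis=1)
        calls["site_label"] = np.where(m < model.tau, "under_methylated", "full")
        calls.loc[
            (calls["plus_label"] == "no_data") | (calls["minus_label"] == "no_data"),
            "site_label",
        ] = "no_data"
        return calls

    plus_u = calls["plus_label"] == "under_methylated"
    minus_u = calls["minus_label"] == "under_methylated"
    nodata = (calls["plus_label"] == "no_data") | (calls["minus_label"] == "no_data")
    label = np.select(
        [nodata, plus_u & minus_u, plus_u ^ minus_u],
        ["no_data", "under_methylated", "asymmetric"],
        default="full",
    )
    calls["site_label"] = label
    return calls


def site_class_tally(motif_calls: pd.DataFrame) -> dict[str, int]:
    counts = motif_calls["site_label"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in SITE_LABELS}


def window_profile(
    observations: pd.DataFrame,
    model: CalibrationModel,
    window: int = 20_000,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Average IPD ratio in fixed non-overlapping tiles along the contig.

    percent_full rescales the window mean so that r_full maps to 100%
    (fully methylated population) and r_hemi to 0% (uniformly
    hemi-methylated population).
    """
    if chrom_length is None:
        chrom_length = int(observations["position"].max()) + 1
    n_win = int(np.ceil(chrom_length / window))
    starts = np.arange(n_win) * window
    ends = np.minimum(starts + window, chrom_length)
    idx = (observations["position"].to_numpy(int) % chrom_length) // window

    mean_ratio = np.full(n_win, np.nan)
    n_obs = np.zeros(n_win, dtype=int)
    grouped = observations.groupby(idx)["ipd_ratio"]
    means = grouped.mean()
    sizes = grouped.size()
    mean_ratio[means.index.to_numpy(int)] = means.to_numpy(float)
    n_obs[sizes.index.to_numpy(int)] = sizes.to_numpy(int)

    percent = 100.0 * (mean_ratio - model.r_hemi) / (model.r_full - model.r_hemi)
    return pd.DataFrame(
        {
            "start": starts,
            "end": ends,
            "midpoint": (starts + ends) / 2.0,
            "mean_ratio": mean_ratio,
            "percent_full": percent,
            "n_obs": n_obs,
        }
    )


def _tricube_local_linear(x: np.ndarray, y: np.ndarray, x0: np.ndarray, k: int) -> np.ndarray:
    """LOESS degree 1: k-nearest-neighbour tricube weights, WLS line fit."""
    out = np.empty(len(x0))
    for i, xi in enumerate(x0):
        d = np.abs(x - xi)
        nn = np.argpartition(d, min(k, len(x)) - 1)[:k]
        h = d[nn].max()
        if h == 0:
            out[i] = y[nn].mean()
            continue
        w = (1 - (d[nn] / h) ** 3) ** 3
        xs, ys = x[nn], y[nn]
        # weighted simple linear regression about xi
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        if sxx <= 0:
            out[i] = ym
        else:
            b = (w * (xs - xm) * (ys - ym)).sum() / sxx
            out[i] = ym + b * (xi - xm)
    return out


def smooth_profile(
    profile: pd.DataFrame,
    span: float = 0.75,
    circular: bool = True,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """LOESS-smooth percent_full over window midpoints.

    The bandwidth covers ``ceil(span * n)`` of the n non-empty windows.
    On circular contigs one bandwidth-width of windows is mirrored across
    the origin junction before fitting, so the smooth is continuous there.
    Returns the profile with a ``smoothed_percent`` column (NaN for empty
    windows).
    """
    ok = profile["n_obs"] > 0
    x = profile.loc[ok, "midpoint"].to_numpy(float)
    y = profile.loc[ok, "percent_full"].to_numpy(float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 non-empty windows, got {n}")
    k = max(2, min(n, int(np.ceil(span * n))))

    if circular:
        if chrom_length is None:
            chrom_length = int(profile["end"].max())
        pad = min(k, n)
        xa = np.concatenate([x[-pad:] - chrom_length, x, x[:pad] + chrom_length])
        ya = np.concatenate([y[-pad:], y, y[:pad]])
    else:
        xa, ya = x, y

    smoothed = _tricube_local_linear(xa, ya, x, k)
    out = profile.copy()
    out["smoothed_percent"] = np.nan
    out.loc[ok, "smoothed_percent"] = smoothed
    return out


def origin_gradient_stat(
    positions,
    f_meth,
    origin: int,
    chrom_length: int,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of distance-to-origin vs methylated fraction.

    A replication-timing gradient (early-replicated, origin-proximal sites
    spending longest hemi-methylated) shows up as rho > 0. The p-value is
    a two-sided permutation p over ``n_permutations`` shuffles of f.
    """
    positions = np.asarray(positions, dtype=float)
    f = np.asarray(f_meth, dtype=float)
    ok = np.isfinite(f)
    positions, f = positions[ok], f[ok]
    d = circular_distance(positions, origin, chrom_length)
    if np.all(f == f[0]) or np.all(d == d[0]):
        return 0.0, 1.0
    rd = stats.rankdata(d)
    rf = stats.rankdata(f)
    rd_c = rd - rd.mean()
    rf_c = rf - rf.mean()
    norm = np.sqrt((rd_c**2).sum() * (rf_c**2).sum())
    rho = float((rd_c @ rf_c) / norm)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rho_p = (rd_c @ rng.permutation(rf_c)) / norm
        if abs(rho_p) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)
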