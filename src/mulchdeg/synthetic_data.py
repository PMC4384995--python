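"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the laboratory study design this package
quantifies: scanned black polyester films developing holes and tears
(known degraded-area fraction), dilution plates with Poisson colony
counts and binomial clear-zone degrader colonies, a 4-week incubation
time course in which the degrader population grows logistically only
when film is buried, and multi-soil datasets whose degrader isolation
rate and film degradation rate share a prescribed rank correlation
(Gaussian copula on ranks).

Every generator takes an explicit seed and emits its ground truth next to
the data, so downstream stages can be tested by parameter recovery alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .esterase_assay import AssayConfig, absorbance_from_activity
from .film_quant import FilmImage

__all__ = [
    "FilmSimSpec",
    "SoilSimSpec",
    "FilmGroundTruth",
    "simulate_film_image",
    "simulate_plates",
    "simulate_timecourse",
    "simulate_multisoil",
]


# ---------------------------------------------------------------------------
# film images


@dataclass(frozen=True)
class FilmSimSpec:
    """Synthetic scan of a black film piece on a light background.

    The film is a centred rectangle larger than the default 300-px
    analysis ROI, so a fresh-film ROI sees film only.  Holes are random
    disks plus thin rectangular tears; their in-film area fraction is
    adjusted to ``degraded_fraction`` to within one pixel.
    """

    image_size: tuple[int, int] = (400, 400)
    film_size: tuple[int, int] = (320, 320)
    gray_film: float = 30.0
    gray_background: float = 200.0
    degraded_fraction: float = 0.0
    hole_radius_mean: float = 3.0
    tear_fraction: float = 0.15  # share of shapes drawn as thin tears
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degraded_fraction <= 1.0:
            raise ValueError("degraded_fraction must lie in [0, 1]")
        if self.gray_film == self.gray_background:
            raise ValueError("film and background gray values must differ")
        if any(f > i for f, i in zip(self.film_size, self.image_size)):
            raise ValueError("film must fit inside the image")


@dataclass
class FilmGroundTruth:
    film_mask: np.ndarray  # True where the (intact or degraded) film lies
    hole_mask: np.ndarray  # True where film has degraded away
    degraded_fraction: float  # realised in-film hole area fraction


def simulate_film_image(spec: FilmSimSpec, max_shapes: int = 20_000) -> tuple[FilmImage, FilmGroundTruth]:
    """Render a noisy film scan plus its exact degradation mask."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    fh, fw = spec.film_size
    r0, c0 = (H - fh) // 2, (W - fw) // 2
    film = np.zeros((H, W), dtype=bool)
    film[r0 : r0 + fh, c0 : c0 + fw] = True
    holes = np.zeros((H, W), dtype=bool)

    target = int(round(spec.degraded_fraction * film.sum()))
    if target >= film.sum():  # fully degraded
        holes[:] = film
    else:
        # hole centres are sampled from a margin-padded rectangle so the
        # film border is not systematically hole-poor (edge effect)
        pad = int(3 * spec.hole_radius_mean)
        n_shapes = 0
        hole_count = 0
        while hole_count < target:
            n_shapes += 1
            if n_shapes > max_shapes:
                raise RuntimeError(
                    "could not reach the requested degraded fraction; "
                    "hole placement exhausted its retry budget"
                )
            rr = int(rng.integers(r0 - pad, r0 + fh + pad))
            cc = int(rng.integers(c0 - pad, c0 + fw + pad))
            is_disk = rng.random() >= spec.tear_fraction
            if is_disk:
                radius = max(1.0, rng.exponential(spec.hole_radius_mean))
                hh = hw = int(math.ceil(radius))
            else:
                # thin tear: elongated axis-aligned rectangle
                length = max(2, int(rng.exponential(8 * spec.hole_radius_mean)))
                width = max(1, int(rng.exponential(1.2)))
                hh, hw = ((width, length // 2) if rng.random() < 0.5
                          else (length // 2, width))
            # local stamping window, clipped to the image
            rlo, rhi = max(rr - hh, 0), min(rr + hh + 1, H)
            clo, chi = max(cc - hw, 0), min(cc + hw + 1, W)
            if rlo >= rhi or clo >= chi:
                continue
            rows = np.arange(rlo, rhi)[:, None]
            cols = np.arange(clo, chi)[None, :]
            if is_disk:
                patch = (rows - rr) ** 2 + (cols - cc) ** 2 <= radius**2
            else:  # tear rectangle
                patch = (np.abs(rows - rr) <= hh) & (np.abs(cols - cc) <= hw)
            window = holes[rlo:rhi, clo:chi]
            new = patch & film[rlo:rhi, clo:chi] & ~window
            window |= new
            hole_count += int(new.sum())
        # trim the overshoot so the realised fraction is exact to one pixel
        excess = hole_count - target
        if excess > 0:
            hr, hc = np.nonzero(holes)
            drop = rng.choice(hr.size, size=excess, replace=False)
            holes[hr[drop], hc[drop]] = False

    img = np.full((H, W), spec.gray_background, dtype=float)
    img[film & ~holes] = spec.gray_film
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 255.0, out=img)
    realised = float(holes.sum() / film.sum())
    truth = FilmGroundTruth(film_mask=film, hole_mask=holes, degraded_fraction=realised)
    return FilmImage(pixels=img, id=f"sim_f{spec.degraded_fraction:g}_s{spec.seed}"), truth


# ---------------------------------------------------------------------------
# soils


@dataclass(frozen=True)
class SoilSimSpec:
    """Study-level simulation parameters.

    Magnitudes follow the cross-soil ranges the pipeline is built for:
    total culturable fungi of order 3e4-2e5 CFU per g dry soil, degrader
    shares of roughly 4-45 % of the total, esterase activities of tens to
    ~160 nmol per g dry soil per min, a 4-week incubation, and triplicate
    assays per time point.
    """

    n_soils: int = 11
    total_density_geomean: float = 7.0e4  # CFU per g dry soil
    total_density_gsd: float = 1.8  # geometric SD across soils
    degrader_fraction_range: tuple[float, float] = (0.04, 0.45)
    logistic_rate_per_week: float = 1.5  # with-film degrader growth rate
    carrying_capacity_factor: float = 20.0  # K relative to the baseline density
    baseline_activity: float = 40.0  # nmol g^-1 min^-1 at week 0
    activity_per_degrader: float = 2.0e-3  # nmol g^-1 min^-1 per CFU g^-1
    degradation_per_exposure: float = 20.0  # ratio % per unit relative exposure
    count_noise_sd_log: float = 0.15  # lognormal sigma on replicate counts
    absorbance_noise_sd_log: float = 0.10  # lognormal sigma on activities
    ratio_noise_sd: float = 2.0  # additive scanner noise on ratios (%)
    water_content_fraction: float = 0.30
    wet_mass_g: float = 1.0
    suspension_volume_ml: float = 10.0
    volume_plated_ml: float = 0.1
    target_rank_correlation: float = 0.63
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_density_geomean <= 0:
            raise ValueError("densities must be positive")
        if self.logistic_rate_per_week < 0:
            raise ValueError("logistic rate must be >= 0")
        if not -1.0 <= self.target_rank_correlation <= 1.0:
            raise ValueError("target rank correlation must lie in [-1, 1]")


def _suspension_concentration_per_ml(density_per_g_dry: float, spec: SoilSimSpec) -> float:
    dry_mass = spec.wet_mass_g * (1.0 - spec.water_content_fraction)
    return density_per_g_dry * dry_mass / spec.suspension_volume_ml


def simulate_plates(
    spec: SoilSimSpec,
    dilutions: list[float],
    n_plates: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dilution-plate colony counts for ``spec.n_soils`` soils.

    Counts are Poisson with mean = suspension concentration x plated
    volume / dilution; clear-zone colonies are binomial with the soil's
    true degrader fraction.  Returns (plate table in the counts-pipeline
    schema, per-soil ground-truth table).
    """
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.degrader_fraction_range
    rows, truths = [], []
    for s in range(spec.n_soils):
        soil = f"S{s + 1:02d}"
        total = float(
            spec.total_density_geomean
            * math.exp(rng.normal(0.0, math.log(spec.total_density_gsd)))
        )
        frac = float(rng.uniform(lo, hi))
        truths.append(dict(soil_id=soil, true_total_cfu_per_g_dry=total,
                           true_degrader_fraction=frac))
        conc = _suspension_concentration_per_ml(total, spec)
        for dil in dilutions:
            lam = conc * spec.volume_plated_ml / dil
            for _ in range(n_plates):
                n_col = int(rng.poisson(lam))
                n_clear = int(rng.binomial(n_col, frac)) if n_col else 0
                rows.append(dict(
                    soil_id=soil, medium="fungal", dilution_factor=dil,
                    volume_plated_ml=spec.volume_plated_ml,
                    colonies_total=n_col, colonies_clearing=n_clear,
                    wet_mass_g=spec.wet_mass_g,
                    suspension_volume_ml=spec.suspension_volume_ml,
                    water_content_fraction=spec.water_content_fraction,
                ))
    return pd.DataFrame(rows), pd.DataFrame(truths)


def _logistic(d0: float, rate: float, capacity: float, t: np.ndarray) -> np.ndarray:
    e = np.exp(rate * t)
    return capacity * d0 * e / (capacity + d0 * (e - 1.0))


def simulate_timecourse(
    spec: SoilSimSpec,
    weeks: range | list[int] = range(0, 5),
    n_replicates: int = 3,
    assay_config: AssayConfig | None = None,
    soil_id: str = "SIM",
) -> dict[str, pd.DataFrame]:
    """One soil's 4-week incubation with and without a buried film.

    With film, the degrader density grows logistically from its baseline;
    without film it stays stationary around the baseline.  Esterase
    activity is baseline + increment x degrader density, rendered as
    blank/background-bracketed absorbance readings by inverting the assay
    conversion.  The weekly degradation ratio tracks cumulative degrader
    exposure, which is near-linear over the first three weeks.

    Returns a dict with ``counts`` (long per-replicate degrader counts),
    ``absorbance`` (assay-schema readings), ``degradation`` (per-replicate
    ratios, with-film only) and ``truth`` (noise-free weekly values).
    """
    rng = np.random.default_rng(spec.seed)
    cfg = assay_config or AssayConfig(water_content_fraction=spec.water_content_fraction)
    weeks = np.asarray(list(weeks))
    lo, hi = spec.degrader_fraction_range
    d0 = spec.total_density_geomean * 0.5 * (lo + hi)
    capacity = d0 * spec.carrying_capacity_factor
    dens = {"with_film": _logistic(d0, spec.logistic_rate_per_week, capacity,
                                   weeks.astype(float)),
            "without_film": np.full(weeks.size, d0)}
    act = {trt: spec.baseline_activity + spec.activity_per_degrader * d
           for trt, d in dens.items()}
    # cumulative degrader exposure (relative to carrying capacity) drives
    # the degradation ratio; with saturating growth this is near-linear
    # after the first week
    rel = dens["with_film"] / capacity
    exposure = np.concatenate([[0.0], np.cumsum(rel[1:] if weeks[0] == 0 else rel)])[
        : weeks.size
    ]
    ratio_true = np.minimum(100.0, spec.degradation_per_exposure * exposure)

    counts_rows, abs_rows, deg_rows, truth_rows = [], [], [], []
    a_blank, a_background = 0.05, 0.03
    for wi, w in enumerate(weeks):
        for trt in ("with_film", "without_film"):
            for rep in range(n_replicates):
                c = dens[trt][wi] * math.exp(rng.normal(0, spec.count_noise_sd_log))
                counts_rows.append(dict(soil_id=soil_id, week=int(w), treatment=trt,
                                        replicate=rep,
                                        degrader_cfu_per_g_dry=float(c)))
                a = act[trt][wi] * math.exp(
                    rng.normal(0, spec.absorbance_noise_sd_log)
                )
                abs_rows.append(dict(
                    soil_id=soil_id, timepoint_week=int(w), treatment=trt,
                    replicate=rep,
                    a_sample=absorbance_from_activity(a, cfg) + a_blank + a_background,
                    a_blank=a_blank, a_background=a_background,
                ))
            if trt == "with_film":
                for rep in range(n_replicates):
                    deg_rows.append(dict(
                        soil_id=soil_id, week=int(w), replicate=rep,
                        ratio_percent=float(
                            ratio_true[wi] + rng.normal(0, spec.ratio_noise_sd)
                        ),
                    ))
        truth_rows.append(dict(
            week=int(w), degrader_with_film=float(dens["with_film"][wi]),
            degrader_without_film=float(dens["without_film"][wi]),
            activity_with_film=float(act["with_film"][wi]),
            activity_without_film=float(act["without_film"][wi]),
            ratio_percent=float(ratio_true[wi]),
        ))
    return dict(
        counts=pd.DataFrame(counts_rows),
        absorbance=pd.DataFrame(abs_rows),
        degradation=pd.DataFrame(deg_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# multi-soil correlated datasets


def _pearson_for_spearman(target: float, n: int) -> float:
    """Bivariate-normal correlation whose *sample* Spearman expectation is
    ``target`` at sample size n.

    Uses E[r_s] = 6 / (pi (n+1)) * [asin(rho) + (n-2) asin(rho/2)] for the
    bivariate normal; for large n this approaches the usual
    2 sin(pi rho_s / 6) inversion.
    """
    if target == 0.0:
        return 0.0
    if abs(target) >= 1.0:
        return math.copysign(1.0, target)

    def expected_rs(rho: float) -> float:
        return 6.0 / (math.pi * (n + 1)) * (
            math.asin(rho) + (n - 2) * math.asin(rho / 2.0)
        )

    # expected_rs(+/-1) = +/-1 exactly, so a root always brackets
    lo, hi = (0.0, 1.0) if target > 0 else (-1.0, 0.0)
    return float(optimize.brentq(lambda r: expected_rs(r) - target, lo, hi))


def simulate_multisoil(
    spec: SoilSimSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-soil isolation and degradation rates with a target rank correlation.

    A Gaussian copula couples the two quantities: latent bivariate-normal
    scores are transformed through uniform marginals into a degrader
    fraction (uniform over ``degrader_fraction_range``) and a degradation
    rate (lognormal, spanning roughly 0.1-20 % per week).  The latent
    correlation is calibrated so the *expected sample* Spearman at
    ``n_soils`` equals ``target_rank_correlation``.

    Returns (per-soil table, info dict with the latent correlation used).
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_soils
    if n < 5:
        raise ValueError("multi-soil simulation needs n >= 5")
    rho_s = spec.target_rank_correlation
    rho_latent = _pearson_for_spearman(rho_s, n)
    z1 = rng.standard_normal(n)
    if abs(rho_latent) == 1.0:  # exactly co-/counter-monotone
        z2 = math.copysign(1.0, rho_latent) * z1
    else:
        z2 = rho_latent * z1 + math.sqrt(1 - rho_latent**2) * rng.standard_normal(n)
    z = np.column_stack([z1, z2])
    u = sps.norm.cdf(z)
    lo, hi = spec.degrader_fraction_range
    frac = lo + (hi - lo) * u[:, 0]
    # lognormal degradation rate: median ~1.5 %/week, x10 spread
    rate = 1.5 * np.exp(sps.norm.ppf(u[:, 1]) * 1.2)
    totals = spec.total_density_geomean * np.exp(
        rng.normal(0.0, math.log(spec.total_density_gsd), size=n)
    )
    df = pd.DataFrame(dict(
        soil_id=[f"S{i + 1:02d}" for i in range(n)],
        cfu_total_per_g_dry=totals,
        cfu_clearing_per_g_dry=totals * frac,
        isolation_rate_percent=100.0 * frac,
        degradation_rate_percent_per_week=rate,
    ))
    # weekly degradation ratios in the film-pipeline schema (weeks 1-4)
    weekly = []
    for _, r in df.iterrows():
        for w in range(1, 5):
            mean = min(100.0, r["degradation_rate_percent_per_week"] * w)
            weekly.append(dict(soil_id=r["soil_id"], week=w,
                               mean_ratio_percent=mean,
                               se_percent=spec.ratio_noise_sd / math.sqrt(3)))
    info = dict(latent_pearson=rho_latent, target_spearman=rho_s,
                weekly=pd.DataFrame(weekly))
    return df, info
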