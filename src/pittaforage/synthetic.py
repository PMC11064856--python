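"""Seeded generator of feeding-visit datasets with realistic marginal structure.

The generator emulates the structure of a nest-camera provisioning study of
a vermivorous forest bird: a handful of nests, each observed on several days
(one observation session per nest-day), with every parental visit delivering
a beak-load of prey.  Its defaults target the marginal statistics of such a
study:

* visit-type shares ``OnlyE`` 0.648 / ``MIX`` 0.305 / ``NoE`` 0.047, with
  non-earthworm and mixed loads enriched for older broods;
* inter-visit intervals with mean ~35 min, SD ~26 min (gamma-shaped),
  shorter in the morning and for old broods;
* earthworm-only loads of 1-6 worms (mean ~2.6, median 2), fewer worms per
  load on heavy-rain days;
* mixed loads of 2-7 items (mean ~3.4); no-earthworm loads of one item;
* earthworm lengths quantised to 0.5 cm (max 15.5 cm) with marginal mean
  ~6.34 cm and SD ~2.5 cm, longer worms on heavy-rain days and a negative
  within-load coupling between worm count and worm length so that total
  load biomass is roughly independent of the count;
* non-earthworm prey lengths with mean ~3.59 cm, SD ~2.4 cm.

Class-conditional parameters are solved from the marginal targets at
configuration time (see ``_Resolved``), so the configured effects (age,
rain, time of day) and the marginal targets hold simultaneously in
expectation.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TAXA, FeedingVisit, NestObservation, classify_visit
from .io import visits_from_frame, COLUMNS

__all__ = ["SyntheticConfig", "generate", "recovery_report"]

_WORM_SUPPORT = np.arange(1, 7)  # worms per OnlyE load
_MIX_EXTRA_SUPPORT = np.arange(1, 7)  # items beyond the first in a MIX load

#: Non-earthworm taxa sampling weights (centipedes most common, a thin tail
#: of rarer taxa including the occasional vertebrate).
_OTHER_TAXA = [t for t in TAXA if t != "earthworm"]
_OTHER_WEIGHTS = np.array([0.34, 0.17, 0.12, 0.10, 0.06, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01])


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic feeding-visit generator.

    Marginal targets are *dataset-wide* expectations; the generator derives
    class-conditional (age, rain, count) parameters from them.
    """

    n_nests: int = 4
    brood_sizes: tuple[int, ...] = (5, 5, 6, 5)
    nestling_period_days: int = 12
    sessions_per_nest: int = 8
    session_hours_range: tuple[float, float] = (3.0, 6.0)
    session_start_range: tuple[float, float] = (8.0, 12.0)
    heavy_rain_day_probability: float = 0.3

    # visit-type marginal shares and old-age enrichment (odds multipliers)
    visit_type_shares: dict = field(
        default_factory=lambda: {"OnlyE": 0.648, "MIX": 0.305, "NoE": 0.047}
    )
    old_visit_type_odds: dict = field(
        default_factory=lambda: {"OnlyE": 1.0, "MIX": 1.5, "NoE": 4.0}
    )

    # inter-visit interval (minutes)
    interval_mean_min: float = 35.0
    interval_sd_min: float = 26.0
    interval_morning_factor: float = 0.8
    interval_old_factor: float = 0.85
    interval_max_min: float = 150.0

    # worms per OnlyE load (truncated-geometric on 1..6)
    worms_per_onlye_mean: float = 2.6
    worms_heavy_rain_factor: float = 0.8

    # items per MIX load (1 + truncated-geometric on 1..6 -> support 2..7)
    mix_items_mean: float = 3.4

    # earthworm length (cm, quantised to 0.5, truncated to [0.5, 15.5])
    worm_length_mean_cm: float = 6.34
    worm_length_sd_cm: float = 2.50
    worm_length_max_cm: float = 15.5
    worm_length_heavy_rain_factor: float = 1.15
    #: exponent of the within-load count-length coupling; 1/3.19 keeps the
    #: allometric total load biomass approximately count-invariant
    length_count_exponent: float = 1.0 / 3.19

    # non-earthworm prey length (cm, quantised to 0.5)
    other_length_mean_cm: float = 3.59
    other_length_sd_cm: float = 2.40

    # data-quality emulation
    unknown_taxon_probability: float = 0.044
    unmeasured_length_probability: float = 0.02
    sunder_length_threshold_cm: float = 8.0

    first_hatch_date: _dt.date = _dt.date(2021, 5, 20)
    rng_seed: int = 0

    def validate(self) -> None:
        shares = self.visit_type_shares
        if set(shares) != {"OnlyE", "MIX", "NoE"}:
            raise ValueError("visit_type_shares must cover OnlyE/MIX/NoE exactly")
        if any(not (0 <= v <= 1) for v in shares.values()):
            raise ValueError("visit-type shares must lie in [0, 1]")
        if not math.isclose(sum(shares.values()), 1.0, abs_tol=1e-9):
            raise ValueError("visit-type shares must sum to 1")
        if not (0 <= self.heavy_rain_day_probability <= 1):
            raise ValueError("heavy_rain_day_probability must lie in [0, 1]")
        if self.sessions_per_nest > self.nestling_period_days:
            raise ValueError("at most one session per nest-day")
        for mean, lo, hi, what in (
            (self.worms_per_onlye_mean, 1.0, 6.0, "worms_per_onlye_mean"),
            (self.mix_items_mean, 2.0, 7.0, "mix_items_mean"),
        ):
            if not (lo < mean < hi):
                raise ValueError(f"{what}={mean} outside open support ({lo}, {hi})")
        # heavy/light class means must also stay inside the count support
        _resolve(self)


def _trunc_geom_pmf(mean: float, support: np.ndarray) -> np.ndarray:
    """PMF of a geometric distribution truncated to ``support`` with given mean.

    The decay ratio is solved by bisection; the family covers means in the
    open interval (support.min(), support.mean()+...) and is the simplest
    monotone one-parameter count family on a finite support.
    """
    k = support.astype(float)

    def mean_of(log_r: float) -> float:
        w = np.exp(log_r * (k - k[0]))
        w /= w.sum()
        return float((w * k).sum())

    lo, hi = -20.0, 20.0
    if not (mean_of(lo) < mean < mean_of(hi)):
        raise ValueError(f"mean {mean} infeasible on support {support}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_of(mid) < mean:
            lo = mid
        else:
            hi = mid
    w = np.exp(0.5 * (lo + hi) * (k - k[0]))
    return w / w.sum()


def _solve_conditional_shares(
    target: np.ndarray, odds: np.ndarray, w_old: float
) -> tuple[np.ndarray, np.ndarray]:
    """Find young/old visit-type probabilities whose mixture hits the target.

    Old-class probabilities are the young ones reweighted by ``odds``; an
    iterative proportional fit adjusts the young vector until the
    ``w_old``-weighted mixture equals the marginal target.
    """
    q = target.copy()
    for _ in range(500):
        old = q * odds
        old /= old.sum()
        marg = (1 - w_old) * q + w_old * old
        q = q * target / marg
        q /= q.sum()
    old = q * odds
    old /= old.sum()
    marg = (1 - w_old) * q + w_old * old
    if not np.allclose(marg, target, atol=1e-6):
        raise ValueError("visit-type shares infeasible with configured age enrichment")
    return q, old


@dataclass(frozen=True)
class _Resolved:
    """Class-conditional parameters derived from the marginal targets."""

    young_shares: np.ndarray
    old_shares: np.ndarray
    worm_pmf_light: np.ndarray
    worm_pmf_heavy: np.ndarray
    mix_extra_pmf: np.ndarray
    base_interval_mean: float
    # per-worm length means by (rain class, worms-in-load)
    length_mean: dict
    w_old_visits: float


def _resolve(cfg: SyntheticConfig) -> _Resolved:
    f_h = cfg.heavy_rain_day_probability
    # visit-weighted old fraction: old sessions produce visits at shorter
    # intervals, so their share of visits exceeds their share of days
    period = cfg.nestling_period_days
    old_days = max(0, period - 7)
    w_old_days = old_days / period
    rate_ratio = 1.0 / cfg.interval_old_factor
    w_old = w_old_days * rate_ratio / (w_old_days * rate_ratio + (1 - w_old_days))

    order = ["OnlyE", "MIX", "NoE"]
    target = np.array([cfg.visit_type_shares[k] for k in order])
    odds = np.array([cfg.old_visit_type_odds[k] for k in order])
    young, old = _solve_conditional_shares(target, odds, w_old)

    # rain-conditional worm counts with the configured marginal mean
    mean_l = cfg.worms_per_onlye_mean / (
        f_h * cfg.worms_heavy_rain_factor + (1 - f_h)
    )
    mean_h = mean_l * cfg.worms_heavy_rain_factor
    pmf_l = _trunc_geom_pmf(mean_l, _WORM_SUPPORT)
    pmf_h = _trunc_geom_pmf(mean_h, _WORM_SUPPORT)

    mix_extra = _trunc_geom_pmf(cfg.mix_items_mean - 1.0, _MIX_EXTRA_SUPPORT)

    # worm-count pmf of MIX loads: worms = 1 + Binomial(extra - 1, 1/2)
    from scipy import stats as _st

    mix_worm_pmf = np.zeros(len(_WORM_SUPPORT))
    for e, pe in zip(_MIX_EXTRA_SUPPORT, mix_extra):
        for w in range(1, int(e) + 1):
            mix_worm_pmf[w - 1] += pe * _st.binom.pmf(w - 1, int(e) - 1, 0.5)
    mix_worm_pmf /= mix_worm_pmf.sum()

    # expected interval multiplier, used to centre the marginal interval mean:
    # morning fraction of observed time from the session start/length ranges
    s_lo, s_hi = cfg.session_start_range
    h_mean = 0.5 * sum(cfg.session_hours_range)
    morn = max(0.0, min(10.0, s_hi) - s_lo)  # starts within the morning window
    morning_time_frac = (0.5 * morn**2 / (s_hi - s_lo)) / h_mean if morn > 0 else 0.0
    m_frac = morning_time_frac / cfg.interval_morning_factor
    m_frac = m_frac / (m_frac + (1 - morning_time_frac))
    e_mult = (m_frac * cfg.interval_morning_factor + (1 - m_frac)) * (
        w_old * cfg.interval_old_factor + (1 - w_old)
    )
    # Renewal censoring correction: only gaps completed inside the session
    # window are recorded, and the discarded boundary-straddling gap is
    # length-biased (expected length mu * (1 + cv^2)).  With ~T/mu recorded
    # gaps per session, the recorded mean is approximately
    # mu * (1 - cv^2 * mu / T); invert that for the target marginal mean.
    cv2 = (cfg.interval_sd_min / cfg.interval_mean_min) ** 2
    t_min = h_mean * 60.0
    mu = cfg.interval_mean_min
    for _ in range(20):
        mu = cfg.interval_mean_min + cv2 * mu**2 / t_min
    base_mean = mu / e_mult

    # per-worm length means: rain shift on top of a count coupling
    # m(rain, n) = c_rain * n ** (-length_count_exponent), with c_rain solved
    # so each rain class hits its mean and the classes mix to the marginal.
    gamma = cfg.length_count_exponent
    worm_frac_h = f_h * mean_h / (f_h * mean_h + (1 - f_h) * mean_l)
    mean_len_l = cfg.worm_length_mean_cm / (
        worm_frac_h * cfg.worm_length_heavy_rain_factor + (1 - worm_frac_h)
    )
    mean_len_h = mean_len_l * cfg.worm_length_heavy_rain_factor
    length_mean = {}
    s_only = cfg.visit_type_shares["OnlyE"]
    s_mix = cfg.visit_type_shares["MIX"]
    for rain, pmf, m_target in (
        ("light", pmf_l, mean_len_l),
        ("heavy", pmf_h, mean_len_h),
    ):
        k = _WORM_SUPPORT.astype(float)
        # combined worm-count-in-load distribution over OnlyE and MIX loads
        # (MIX counts do not depend on rain), per-worm weighted
        load_pmf = s_only * pmf + s_mix * mix_worm_pmf
        load_pmf /= load_pmf.sum()
        c = m_target * float((load_pmf * k).sum()) / float(
            (load_pmf * k * k**-gamma).sum()
        )
        for n in _WORM_SUPPORT:
            length_mean[(rain, int(n))] = c * float(n) ** -gamma

    return _Resolved(
        young_shares=young,
        old_shares=old,
        worm_pmf_light=pmf_l,
        worm_pmf_heavy=pmf_h,
        mix_extra_pmf=mix_extra,
        base_interval_mean=base_mean,
        length_mean=length_mean,
        w_old_visits=w_old,
    )


def _draw_quantised_length(
    rng: np.random.Generator, mean: float, sd: float, max_cm: float
) -> float:
    """Gamma length draw, truncated to [0.5, max] and quantised to 0.5 cm."""
    shape = (mean / sd) ** 2
    scale = mean / shape
    x = rng.gamma(shape, scale)
    x = min(max(x, 0.5), max_cm)
    return round(x * 2) / 2


def _draw_session_visits(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    res: _Resolved,
    nest_id: str,
    date: _dt.date,
    age: int,
    brood: int,
    rain_mm: float,
    start_h: float,
    hours: float,
) -> list[dict]:
    heavy = rain_mm > 4.0
    old = age >= 8
    shares = res.old_shares if old else res.young_shares
    worm_pmf = res.worm_pmf_heavy if heavy else res.worm_pmf_light
    rain_key = "heavy" if heavy else "light"

    rows: list[dict] = []
    t = start_h + float(rng.uniform(0, 10.0))/60.0
    end = start_h + hours
    visit_order = 0
    interval: float | None = None
    while t <= end:
        visit_order += 1
        vtype = ["OnlyE", "MIX", "NoE"][int(rng.choice(3, p=shares))]
        if vtype == "OnlyE":
            n_worms = int(rng.choice(_WORM_SUPPORT, p=worm_pmf))
            taxa = ["earthworm"] * n_worms
        elif vtype == "MIX":
            n_items = 1 + int(rng.choice(_MIX_EXTRA_SUPPORT, p=res.mix_extra_pmf))
            n_worms = 1 + int(rng.binomial(max(n_items - 2, 0), 0.5))
            n_worms = min(n_worms, n_items - 1)
            taxa = ["earthworm"] * n_worms + list(
                rng.choice(_OTHER_TAXA, size=n_items - n_worms, p=_OTHER_WEIGHTS)
            )
        else:
            n_worms = 0
            taxa = [str(rng.choice(_OTHER_TAXA, p=_OTHER_WEIGHTS))]

        hh = int(t)
        mm = int(round((t - hh) * 60))
        if mm == 60:
            hh, mm = hh + 1, 0
        for taxon in taxa:
            is_worm = taxon == "earthworm"
            if is_worm:
                m = res.length_mean[(rain_key, max(n_worms, 1))]
                # within-load spread narrower than the marginal SD; the
                # count coupling supplies the between-load variance
                length = _draw_quantised_length(
                    rng, m, cfg.worm_length_sd_cm * 0.85, cfg.worm_length_max_cm
                )
            else:
                length = _draw_quantised_length(
                    rng,
                    cfg.other_length_mean_cm,
                    cfg.other_length_sd_cm,
                    cfg.worm_length_max_cm,
                )
            unmeasured = rng.uniform() < cfg.unmeasured_length_probability
            if not is_worm and rng.uniform() < cfg.unknown_taxon_probability:
                taxon = "unknown"
            pieces = 1
            if is_worm and length >= cfg.sunder_length_threshold_cm:
                pieces = int(rng.integers(2, 4))
            rows.append(
                {
                    "nest_id": nest_id,
                    "date": date.isoformat(),
                    "visit_order": visit_order,
                    "clock_time": f"{hh:02d}:{mm:02d}",
                    "inter_visit_interval_min": interval,
                    "taxon": taxon,
                    "is_earthworm": int(is_worm),
                    "length_beak_units": None if unmeasured else length / 2.0,
                    "n_sundered_pieces": pieces,
                    "nestling_age_days": age,
                    "brood_size": brood,
                    "rainfall_mm": rain_mm,
                    "recorded_hours_day": round(hours, 2),
                }
            )

        mult = 1.0
        if t < 10.0:
            mult *= cfg.interval_morning_factor
        if old:
            mult *= cfg.interval_old_factor
        mean = res.base_interval_mean * mult
        shape = (cfg.interval_mean_min / cfg.interval_sd_min) ** 2
        gap = rng.gamma(shape, mean / shape)
        gap = float(np.clip(round(gap), 1, cfg.interval_max_min))
        interval = gap
        t += gap / 60.0
    return rows


def generate(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[FeedingVisit], list[NestObservation], pd.DataFrame]:
    """Generate a synthetic feeding-visit dataset.

    Returns typed visits, nest observations, and the raw item-row table in
    the CSV interchange schema.  Identical ``(config, seed)`` gives an
    identical dataset; per-nest substreams are spawned deterministically
    from the dataset seed.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    if seed is not None:
        cfg = dataclasses.replace(cfg, rng_seed=int(seed))
    res = _resolve(cfg)
    root = np.random.default_rng(cfg.rng_seed)
    nest_seeds = root.integers(0, 2**31 - 1, size=cfg.n_nests)

    all_rows: list[dict] = []
    for i in range(cfg.n_nests):
        rng = np.random.default_rng(int(nest_seeds[i]))
        nest_id = f"nest{i + 1}"
        brood = int(cfg.brood_sizes[i % len(cfg.brood_sizes)])
        hatch = cfg.first_hatch_date + _dt.timedelta(days=9 * i)
        days = sorted(
            rng.choice(
                np.arange(1, cfg.nestling_period_days + 1),
                size=cfg.sessions_per_nest,
                replace=False,
            ).tolist()
        )
        for age in days:
            date = hatch + _dt.timedelta(days=age - 1)
            heavy = rng.uniform() < cfg.heavy_rain_day_probability
            if heavy:
                rain_mm = round(4.0 + float(rng.exponential(6.0)), 1)
            else:
                rain_mm = 0.0 if rng.uniform() < 0.6 else round(float(rng.uniform(0, 4.0)), 1)
            start = float(rng.uniform(*cfg.session_start_range))
            hours = float(rng.uniform(*cfg.session_hours_range))
            hours = min(hours, 18.0 - start - 0.1)
            all_rows.extend(
                _draw_session_visits(
                    rng, cfg, res, nest_id, date, int(age), brood, rain_mm, start, hours
                )
            )

    frame = pd.DataFrame(all_rows)
    # session_order = index of the observation day within each nest
    so = (
        frame.groupby("nest_id")["date"]
        .transform(lambda s: s.astype("category").cat.codes + 1)
    )
    frame["session_order"] = so
    frame = frame[COLUMNS]
    visits, nests, _ = visits_from_frame(frame)
    return visits, nests, frame


def recovery_report(
    visits: list[FeedingVisit], config: SyntheticConfig
) -> pd.DataFrame:
    """Empirical-vs-target comparison for a generated dataset.

    Tolerances combine the Monte-Carlo standard error at the realised sample
    size (3 SE) with a small systematic allowance for truncation,
    quantisation and the approximations in the class-conditional solver.
    """
    cfg = config
    vt = pd.Series([v.visit_type.value for v in visits])
    n_vis = len(visits)
    rows = []

    for k, target in cfg.visit_type_shares.items():
        emp = float((vt == k).mean())
        tol = 3 * math.sqrt(target * (1 - target) / n_vis) + 0.01
        rows.append(("share_" + k, emp, target, tol))

    iv = np.array(
        [v.inter_visit_interval_min for v in visits if v.inter_visit_interval_min]
    )
    rows.append(
        (
            "interval_mean_min",
            float(iv.mean()),
            cfg.interval_mean_min,
            3 * iv.std() / math.sqrt(len(iv)) + 2.0,
        )
    )
    rows.append(
        ("interval_sd_min", float(iv.std(ddof=1)), cfg.interval_sd_min, 6.0)
    )

    worm_len = np.array(
        [
            it.length_cm
            for v in visits
            for it in v.items
            if it.is_earthworm and it.length_cm is not None
        ]
    )
    rows.append(
        (
            "worm_length_mean_cm",
            float(worm_len.mean()),
            cfg.worm_length_mean_cm,
            3 * worm_len.std() / math.sqrt(len(worm_len)) + 0.15,
        )
    )

    onlye = [v for v in visits if v.visit_type.value == "OnlyE"]
    worms = np.array([v.n_earthworms for v in onlye])
    rows.append(
        (
            "worms_per_onlye_mean",
            float(worms.mean()),
            cfg.worms_per_onlye_mean,
            3 * worms.std() / math.sqrt(len(worms)) + 0.1,
        )
    )

    # rain-effect directions, reported as heavy-minus-light contrasts
    heavy = np.array([v.rainfall_mm > 4.0 for v in onlye])
    if heavy.any() and (~heavy).any():
        rows.append(
            (
                "worms_per_onlye_heavy_minus_light",
                float(worms[heavy].mean() - worms[~heavy].mean()),
                cfg.worms_per_onlye_mean * (cfg.worms_heavy_rain_factor - 1),
                0.35,
            )
        )
        wl_h, wl_l = [], []
        for v in onlye:
            tgt = wl_h if v.rainfall_mm > 4.0 else wl_l
            tgt.extend(
                it.length_cm for it in v.items if it.length_cm is not None
            )
        rows.append(
            (
                "worm_length_heavy_minus_light_cm",
                float(np.mean(wl_h) - np.mean(wl_l)),
                cfg.worm_length_mean_cm
                * (cfg.worm_length_heavy_rain_factor - 1)
                / (1 + 0.0),
                0.8,
            )
        )

    out = pd.DataFrame(rows, columns=["statistic", "empirical", "target", "tolerance"])
    out["within"] = (out["empirical"] - out["target"]).abs() <= out["tolerance"]
    return out
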