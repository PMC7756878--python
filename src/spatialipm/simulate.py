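"""Individual-based simulator for all four data streams.

The simulator runs the generative model forward exactly as it is fitted:
breeders of the modelled sex occupy continuous locations in a two-habitat
landscape; each year they reproduce (Bernoulli success, shifted-Poisson
brood), survive, and disperse by the site-fidelity/Student-T mixture;
fledglings survive and disperse from their natal site; marked individuals
are resighted with zone-dependent detection probability (zero outside the
total study area).  Observed outputs are the territory counts (Poisson
observation error), breeding-success trials/successes, successful-site
brood totals, and wide-format encounter histories with sighting
coordinates.  A truth record retains every latent quantity needed by the
parameter-recovery tests.

Default scenario magnitudes follow the study system this package emulates:
a farmland passerine population of 70-90 pairs in a 60 km^2 area with a
40 km^2 intensively monitored core, breeding success about 0.79 / 0.65
(Short / Tall), 2.8 / 2.45 fledglings per successful site, first-year
survival 0.16-0.21 and breeder survival around 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import special

from .demography import HABITAT_LABELS, VitalRates, build_projection_matrix
from .movement import BREEDER, FLEDGLING, MovementParams, StudyArea
from .multievent import EVENT_NOT_SEEN, EVENT_SEEN_UNDET, DetectionParams

__all__ = [
    "Landscape",
    "SimScenario",
    "SimulatedData",
    "generate_landscape",
    "simulate_dataset",
    "wheatear_scenario",
    "reduced_scenario",
    "closed_scenario",
]


@dataclass
class Landscape:
    """Territory sites scattered over the study area.

    ``sites`` has columns (site, x, y, habitat, in_core).  Habitat labels are
    mixed at fine spatial scale, emulating a mosaic of Short and Tall
    patches.
    """

    area: StudyArea
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        in_core = self.sites["in_core"].to_numpy()
        for h in (0, 1):
            if int(((self.sites["habitat"] == h) & in_core).sum()) < 2:
                raise ValueError("need at least 2 sites per habitat inside the core")


def generate_landscape(
    area: StudyArea | None = None,
    n_core_sites: int = 124,
    n_peripheral_sites: int = 51,
    prop_short: float = 0.6,
    rng_seed=None,
) -> Landscape:
    """Scatter territory sites uniformly in the core and peripheral regions.

    Habitat labels are i.i.d. Bernoulli(prop_short) per site, giving the
    fine-scale Short/Tall mosaic.  Deterministic given the seed.
    """
    if area is None:
        area = StudyArea.default()
    if area.total.area <= 0:
        raise ValueError("zero-area landscape")
    rng = np.random.default_rng(rng_seed)

    def scatter(region, n, exclude=None):
        xmin, ymin, xmax, ymax = region.bounds
        xs, ys = np.empty(n), np.empty(n)
        got = 0
        while got < n:
            cx = rng.uniform(xmin, xmax, size=4 * (n - got))
            cy = rng.uniform(ymin, ymax, size=4 * (n - got))
            ok = shapely.contains_xy(region, cx, cy)
            if exclude is not None:
                ok &= ~shapely.contains_xy(exclude, cx, cy)
            cx, cy = cx[ok], cy[ok]
            take = min(n - got, cx.size)
            xs[got : got + take] = cx[:take]
            ys[got : got + take] = cy[:take]
            got += take
        return xs, ys

    cx, cy = scatter(area.core, n_core_sites)
    rows = [
        pd.DataFrame(
            {
                "x": cx,
                "y": cy,
                "habitat": rng.binomial(1, 1.0 - prop_short, size=n_core_sites),
                "in_core": True,
            }
        )
    ]
    if n_peripheral_sites > 0:
        px, py = scatter(area.total, n_peripheral_sites, exclude=area.core)
        rows.append(
            pd.DataFrame(
                {
                    "x": px,
                    "y": py,
                    "habitat": rng.binomial(1, 1.0 - prop_short, size=n_peripheral_sites),
                    "in_core": False,
                }
            )
        )
    sites = pd.concat(rows, ignore_index=True)
    sites.insert(0, "site", np.arange(len(sites)))
    return Landscape(area=area, sites=sites)


@dataclass
class SimScenario:
    """Generating parameter values and sampling design for one simulation.

    Link-scale intercepts and year-effect standard deviations are indexed
    (Short, Tall).  ``immigration`` optionally supplies external immigrants
    per (year, habitat); the default population is closed to immigration.
    """

    years: int = 15
    start_year: int = 2001
    sex: str = "M"
    seed: int = 0
    initial_nb: tuple[int, int] = (48, 28)
    b_intercept: tuple[float, float] = (special.logit(0.79), special.logit(0.65))
    b_sd: tuple[float, float] = (0.3, 0.3)
    f_intercept: tuple[float, float] = (math.log(2.83), math.log(2.45))
    f_sd: tuple[float, float] = (0.10, 0.10)
    phi_fl_intercept: tuple[float, float] = (special.logit(0.21), special.logit(0.16))
    phi_fl_sd: tuple[float, float] = (0.25, 0.25)
    phi_br_intercept: tuple[float, float] = (special.logit(0.52), special.logit(0.53))
    phi_br_sd: tuple[float, float] = (0.20, 0.20)
    psi_fl: tuple[float, float] = (0.20, 0.30)
    psi_br: tuple[float, float] = (0.05, 0.10)
    movement: MovementParams = field(
        default_factory=lambda: MovementParams(
            sigma_move=np.array([[1.5, 2.0], [0.4, 0.6]]),  # [age, habitat], km
            p_stay=np.array([0.50, 0.35]),
            df=5.0,
        )
    )
    detection: DetectionParams = field(
        default_factory=lambda: DetectionParams(0.90, 0.50, 0.95, 0.80)
    )
    n_mark_fledglings: int = 100  # ringed nestlings per year
    n_mark_breeders: int = 27  # newly ringed breeders per year
    monitor_prob: tuple[float, float] = (0.95, 0.60)  # breeding outcome known (core, periph)
    brood_prob: tuple[float, float] = (0.80, 0.50)  # brood size known given success
    immigration: np.ndarray | None = None
    snap_to_sites: bool = False


@dataclass
class SimulatedData:
    """The four observed data streams plus the latent truth record."""

    counts: pd.DataFrame
    breeding_success: pd.DataFrame
    fledglings: pd.DataFrame
    encounters: pd.DataFrame
    truth: dict
    extinct: bool = False


def wheatear_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The default wheatear-like scenario (full desk scale).

    Local production does not balance mortality plus emigration in this
    system, so the census is held roughly stationary by a constant external
    immigration stream -- mirroring the positive net immigration the study
    population shows.
    """
    base = SimScenario(seed=seed)
    base = replace(base, immigration=np.tile(np.array([7.0, 7.0]), (base.years, 1)))
    return replace(base, **overrides)


def reduced_scenario(seed: int = 0, **overrides) -> SimScenario:
    """A smaller scenario for fast fitting: 10 years, ~600 marked fledglings
    and ~250 marked breeders, population about 40 + 25 pairs."""
    base = SimScenario(
        seed=seed,
        years=10,
        initial_nb=(40, 25),
        n_mark_fledglings=60,
        n_mark_breeders=25,
    )
    base = replace(base, immigration=np.tile(np.array([6.0, 6.0]), (base.years, 1)))
    return replace(base, **overrides)


def closed_scenario(seed: int = 0, reduced: bool = True, **overrides) -> SimScenario:
    """A scenario with no immigration and negligible emigration.

    The total study area is made very large relative to dispersal distances
    so that essentially no movement ends outside it; together with zero
    external immigration this yields a truly closed population.
    """
    base = reduced_scenario(seed) if reduced else SimScenario(seed=seed)
    base = replace(base, immigration=None)
    return replace(base, **overrides)


def closed_area(core_size: tuple[float, float] = (10.0, 6.0)) -> StudyArea:
    """Study area for `closed_scenario`: a normal-sized core patch inside an
    effectively infinite total region."""
    w, h = core_size
    return StudyArea.from_rects((-500.0, 500.0, -500.0, 500.0), (0.0, w, 0.0, h))


def _year_rates(scenario: SimScenario, rng) -> dict[str, np.ndarray]:
    """Draw year effects and return natural-scale yearly rates, shape (years, 2)."""
    y = scenario.years
    out = {}
    for name, (icpt, sd), link in [
        ("b", (scenario.b_intercept, scenario.b_sd), "logit"),
        ("f", (scenario.f_intercept, scenario.f_sd), "log"),
        ("phi_fl", (scenario.phi_fl_intercept, scenario.phi_fl_sd), "logit"),
        ("phi_br", (scenario.phi_br_intercept, scenario.phi_br_sd), "logit"),
    ]:
        icpt = np.asarray(icpt)
        sd = np.asarray(sd)
        eta = icpt[None, :] + rng.normal(0.0, 1.0, size=(y, 2)) * sd[None, :]
        out[name] = special.expit(eta) if link == "logit" else np.exp(eta)
    return out


def simulate_dataset(
    landscape: Landscape, scenario: SimScenario, rng_seed=None
) -> SimulatedData:
    """Run the generative model forward and emit all four data streams."""
    rng = np.random.default_rng(scenario.seed if rng_seed is None else rng_seed)
    area = landscape.area
    y = scenario.years
    rates = _year_rates(scenario, rng)
    psi_fl = np.asarray(scenario.psi_fl)
    psi_br = np.asarray(scenario.psi_br)
    mv = scenario.movement
    det = scenario.detection
    sites = landscape.sites

    # current breeders (arrays); mid = -1 for unmarked
    hab = np.empty(0, dtype=np.int64)
    bx = np.empty(0)
    by = np.empty(0)
    mid = np.empty(0, dtype=np.int64)
    for h in (0, 1):
        cand = sites.index[(sites["habitat"] == h)].to_numpy()
        pick = rng.choice(cand, size=scenario.initial_nb[h], replace=True)
        hab = np.append(hab, np.full(scenario.initial_nb[h], h))
        bx = np.append(bx, sites["x"].to_numpy()[pick])
        by = np.append(by, sites["y"].to_numpy()[pick])
        mid = np.append(mid, np.full(scenario.initial_nb[h], -1))

    max_marked = y * (scenario.n_mark_fledglings + scenario.n_mark_breeders)
    m_events = np.full((max_marked, y), EVENT_NOT_SEEN, dtype=np.int64)
    m_x = np.full((max_marked, y), np.nan)
    m_y = np.full((max_marked, y), np.nan)
    m_year = np.full(max_marked, -1, dtype=np.int64)
    m_age = np.full(max_marked, -1, dtype=np.int64)
    m_hab = np.full(max_marked, -1, dtype=np.int64)
    n_marked = 0

    counts_rows, bs_rows, fl_rows = [], [], []
    nb_truth = np.zeros((y, 2), dtype=np.int64)
    emig_events = np.zeros((2, 2), dtype=np.int64)  # [age, habitat] moves ending outside
    emig_trials = np.zeros((2, 2), dtype=np.int64)  # [age, habitat] surviving movers
    surv_events = np.zeros((2, 2), dtype=np.int64)  # [age, habitat] realized survivors
    surv_trials = np.zeros((2, 2), dtype=np.int64)

    def snap(xs, ys):
        if not scenario.snap_to_sites:
            return xs, ys
        sx = sites["x"].to_numpy()
        sy = sites["y"].to_numpy()
        d2 = (xs[:, None] - sx[None, :]) ** 2 + (ys[:, None] - sy[None, :]) ** 2
        j = d2.argmin(axis=1)
        return sx[j], sy[j]

    for t in range(y):
        inside = area.contains_total(bx, by)
        in_core = area.contains_core(bx, by)
        for h in (0, 1):
            nb_truth[t, h] = int(np.sum(inside & (hab == h)))
            counts_rows.append(
                {
                    "year": scenario.start_year + t,
                    "habitat": HABITAT_LABELS[h],
                    "count": int(rng.poisson(nb_truth[t, h])),
                }
            )

        # --- resight marked breeders ---
        is_marked = mid >= 0
        if np.any(is_marked):
            idx = np.flatnonzero(is_marked & inside)
            p_zone = np.where(in_core[idx], det.p_core, det.p_peripheral)
            c_zone = np.where(in_core[idx], det.c_core, det.c_peripheral)
            seen = rng.random(idx.size) < p_zone
            known = rng.random(idx.size) < c_zone
            for k, i in enumerate(idx):
                if not seen[k]:
                    continue
                ev = (hab[i] + 1) if known[k] else EVENT_SEEN_UNDET
                m_events[mid[i], t] = ev
                m_x[mid[i], t], m_y[mid[i], t] = bx[i], by[i]

        # --- mark new breeders ---
        cand = np.flatnonzero((mid < 0) & inside)
        if cand.size and scenario.n_mark_breeders > 0 and n_marked < max_marked:
            take = min(scenario.n_mark_breeders, cand.size, max_marked - n_marked)
            pick = rng.choice(cand, size=take, replace=False)
            for i in pick:
                mid[i] = n_marked
                m_year[n_marked] = t
                m_age[n_marked] = BREEDER
                m_hab[n_marked] = hab[i]
                m_events[n_marked, t] = hab[i] + 1
                m_x[n_marked, t], m_y[n_marked, t] = bx[i], by[i]
                n_marked += 1

        # --- reproduction ---
        b_t = rates["b"][t]
        f_t = rates["f"][t]
        success = rng.random(hab.size) < b_t[hab]
        brood_total = np.zeros(hab.size, dtype=np.int64)
        s_idx = np.flatnonzero(success)
        brood_total[s_idx] = 1 + rng.poisson(2.0 * f_t[hab[s_idx]] - 1.0, size=s_idx.size)

        # reproduction data: only breeders inside the total area are observable
        monitored = inside & (
            rng.random(hab.size)
            < np.where(in_core, scenario.monitor_prob[0], scenario.monitor_prob[1])
        )
        brood_known = (
            monitored
            & success
            & (
                rng.random(hab.size)
                < np.where(in_core, scenario.brood_prob[0], scenario.brood_prob[1])
            )
        )
        for h in (0, 1):
            mh = monitored & (hab == h)
            bs_rows.append(
                {
                    "year": scenario.start_year + t,
                    "habitat": HABITAT_LABELS[h],
                    "R": int(mh.sum()),
                    "B": int((mh & success).sum()),
                }
            )
            kh = brood_known & (hab == h)
            fl_rows.append(
                {
                    "year": scenario.start_year + t,
                    "habitat": HABITAT_LABELS[h],
                    "S": int(kh.sum()),
                    "F": int(brood_total[kh].sum()),
                }
            )

        # fledglings of the modelled sex
        n_sex = rng.binomial(brood_total, 0.5)
        parent = np.repeat(np.arange(hab.size), n_sex)
        f_hab = hab[parent]
        f_x = bx[parent]
        f_y = by[parent]
        f_mid = np.full(parent.size, -1, dtype=np.int64)

        # --- mark fledglings (ringed as nestlings at brood-monitored sites) ---
        markable = np.flatnonzero(brood_known[parent])
        if markable.size and scenario.n_mark_fledglings > 0 and n_marked < max_marked:
            take = min(scenario.n_mark_fledglings, markable.size, max_marked - n_marked)
            pick = rng.choice(markable, size=take, replace=False)
            for j in pick:
                f_mid[j] = n_marked
                m_year[n_marked] = t
                m_age[n_marked] = FLEDGLING
                m_hab[n_marked] = f_hab[j]
                m_events[n_marked, t] = f_hab[j] + 1
                m_x[n_marked, t], m_y[n_marked, t] = f_x[j], f_y[j]
                n_marked += 1

        if t == y - 1:
            break

        # --- fledgling survival and natal dispersal ---
        phi_fl_t = rates["phi_fl"][t]
        f_inside_before = area.contains_total(f_x, f_y)
        surv = rng.random(f_hab.size) < phi_fl_t[f_hab]
        for h in (0, 1):
            surv_trials[FLEDGLING, h] += int((f_hab == h).sum())
            surv_events[FLEDGLING, h] += int(((f_hab == h) & surv).sum())
        f_hab2 = f_hab[surv]
        f_mid2 = f_mid[surv]
        steps = mv.sigma_move[FLEDGLING, f_hab2][:, None] * rng.standard_t(
            mv.df, size=(f_hab2.size, 2)
        )
        f_x2 = f_x[surv] + steps[:, 0]
        f_y2 = f_y[surv] + steps[:, 1]
        f_x2, f_y2 = snap(f_x2, f_y2)
        switch = rng.random(f_hab2.size) < psi_fl[f_hab2]
        new_hab = np.where(switch, 1 - f_hab2, f_hab2)
        out = ~area.contains_total(f_x2, f_y2)
        started_inside = f_inside_before[surv]
        for h in (0, 1):
            sel = started_inside & (f_hab2 == h)
            emig_trials[FLEDGLING, h] += int(sel.sum())
            emig_events[FLEDGLING, h] += int((sel & out).sum())

        # --- breeder survival and breeding dispersal ---
        phi_br_t = rates["phi_br"][t]
        bsurv = rng.random(hab.size) < phi_br_t[hab]
        for h in (0, 1):
            surv_trials[BREEDER, h] += int((hab == h).sum())
            surv_events[BREEDER, h] += int(((hab == h) & bsurv).sum())
        b_hab2 = hab[bsurv]
        b_mid2 = mid[bsurv]
        b_x2 = bx[bsurv].copy()
        b_y2 = by[bsurv].copy()
        stay = rng.random(b_hab2.size) < mv.p_stay[b_hab2]
        movers = np.flatnonzero(~stay)
        bsteps = mv.sigma_move[BREEDER, b_hab2[movers]][:, None] * rng.standard_t(
            mv.df, size=(movers.size, 2)
        )
        b_inside_before = area.contains_total(b_x2, b_y2)
        b_x2[movers] += bsteps[:, 0]
        b_y2[movers] += bsteps[:, 1]
        if scenario.snap_to_sites:
            b_x2[movers], b_y2[movers] = snap(b_x2[movers], b_y2[movers])
        bswitch = rng.random(b_hab2.size) < psi_br[b_hab2]
        b_newhab = np.where(bswitch, 1 - b_hab2, b_hab2)
        bout = ~area.contains_total(b_x2, b_y2)
        for h in (0, 1):
            # all surviving breeders that started inside are at risk; the ones
            # that stayed cannot emigrate, matching the (1 - Pstay) factor in
            # the model-predicted emigration probability
            sel = b_inside_before & (b_hab2 == h)
            emig_trials[BREEDER, h] += int(sel.sum())
            emig_events[BREEDER, h] += int((sel & bout).sum())

        hab = np.concatenate([b_newhab, new_hab])
        bx = np.concatenate([b_x2, f_x2])
        by = np.concatenate([b_y2, f_y2])
        mid = np.concatenate([b_mid2, f_mid2])

        # --- external immigrants ---
        if scenario.immigration is not None:
            for h in (0, 1):
                n_im = int(scenario.immigration[t + 1, h])
                if n_im > 0:
                    cand_sites = sites.index[sites["habitat"] == h].to_numpy()
                    pick = rng.choice(cand_sites, size=n_im, replace=True)
                    hab = np.append(hab, np.full(n_im, h))
                    bx = np.append(bx, sites["x"].to_numpy()[pick])
                    by = np.append(by, sites["y"].to_numpy()[pick])
                    mid = np.append(mid, np.full(n_im, -1))

    extinct = bool(nb_truth[-1].sum() == 0)

    # assemble encounter table (wide format)
    enc_cols = {
        "id": [f"{scenario.sex}{i:05d}" for i in range(n_marked)],
        "sex": [scenario.sex] * n_marked,
        "mark_year": scenario.start_year + m_year[:n_marked],
        "mark_age": [
            "fledgling" if a == FLEDGLING else "breeder" for a in m_age[:n_marked]
        ],
        "mark_habitat": [HABITAT_LABELS[h] for h in m_hab[:n_marked]],
    }
    for t in range(y):
        yr = scenario.start_year + t
        enc_cols[f"event_{yr}"] = m_events[:n_marked, t]
        enc_cols[f"x_{yr}"] = m_x[:n_marked, t]
        enc_cols[f"y_{yr}"] = m_y[:n_marked, t]
    encounters = pd.DataFrame(enc_cols)
    # events before marking are structurally absent
    for i in range(n_marked):
        for t in range(m_year[i]):
            encounters.iloc[i, 5 + 3 * t] = 0

    a_true = np.zeros((y, 2, 2))
    c_true = np.zeros((y, 2))
    for t in range(y):
        v = VitalRates(
            year=t,
            b=rates["b"][t],
            f=rates["f"][t],
            phi_fl=rates["phi_fl"][t],
            phi_br=rates["phi_br"][t],
            psi_fl=psi_fl,
            psi_br=psi_br,
        )
        a_true[t] = build_projection_matrix(v).a
        c_true[t] = rates["b"][t] * rates["f"][t] * rates["phi_fl"][t] + rates["phi_br"][t]

    with np.errstate(invalid="ignore"):
        emig_rate = np.where(emig_trials > 0, emig_events / np.maximum(emig_trials, 1), np.nan)
    truth = {
        "rates": rates,
        "psi_fl": psi_fl,
        "psi_br": psi_br,
        "movement": mv,
        "detection": det,
        "nb": nb_truth,
        "A": a_true,
        "C": c_true,
        "mean_rates": {k: v.mean(axis=0) for k, v in rates.items()},
        "emigration_rate": emig_rate,
        "emigration_trials": emig_trials,
        "realized_survival": np.where(
            surv_trials > 0, surv_events / np.maximum(surv_trials, 1), np.nan
        ),
        "n_marked": n_marked,
    }
    return SimulatedData(
        counts=pd.DataFrame(counts_rows),
        breeding_success=pd.DataFrame(bs_rows),
        fledglings=pd.DataFrame(fl_rows),
        encounters=encounters,
        truth=truth,
        extinct=extinct,
    )
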