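"""Seeded synthetic studbook generator with known true genetic parameters.

Emulates a closed draught-horse population: a multi-generation pedigree,
recorded mares with annual breeding-season careers (foaling / abortion /
open), and trait values built from additive, dominance, herd (environmental
unit x birth year) and residual components on the lifetime-foaling-rate
(LFR) scale.

Two phenotype routes are provided:

* :func:`simulate_careers` — event-level careers; each mare's per-season
  foaling indicator is Bernoulli with probability
  ``clamp(mu + AF + b_F * F + herd + BV + dom + resid, 0, 1)``.  Realized
  LFR then carries binomial season-sampling noise on top of the liability
  components, as real careers do.
* :func:`simulate_phenotypes` — direct Gaussian trait values on the LFR
  scale with exactly the configured variance components.  This is the
  route for variance-component recovery studies, where the generating
  decomposition itself is the object of interest.

True breeding values follow the pedigree: founders are N(0, var_additive)
and offspring are the parent average plus Mendelian sampling with variance
``0.5 * (1 - (F_s + F_d)/2) * var_additive``.  Dominance deviations are
drawn independently per animal (see module docs for what this does and
does not exercise).  All randomness flows from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import build_A, build_D

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "simulate_pedigree",
    "simulate_careers",
    "simulate_phenotypes",
    "truncate_careers",
    "write_studbook",
    "write_pedigree",
]

#: mean +/- sd of age (months) at first foaling for the two AF classes
AGE3_MONTHS = (36.6, 1.8)
AGE4_MONTHS = (49.0, 2.4)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Variances are on the LFR (proportion) scale; defaults are the
    linear-trait generating components used throughout the test surface
    (herd 0.141e-3, additive 4.848e-3, dominance 1.628e-3, residual
    13.426e-3, i.e. h2 = 0.242).
    """

    n_founders: int = 500
    n_generations: int = 12
    n_recorded_mares_target: int = 3000
    sires_per_generation: int = 80
    #: probability that a dam with an earlier offspring is covered by the
    #: same stallion again (repeat matings produce the full-sib pairs that
    #: identify dominance variance in the analysis)
    repeat_mating_prob: float = 0.5
    eu_count: int = 9
    birth_year_range: tuple[int, int] = (1970, 2014)
    recording_from_year: int = 1990
    p_first_foaling_age3: float = 0.41
    var_herd: float = 0.141e-3
    var_additive: float = 4.848e-3
    var_dominance: float = 1.628e-3
    var_residual: float = 13.426e-3
    inbreeding_depression_slope: float = -0.1
    af4_effect: float = -0.01
    mean_lfr_liability: float = 0.70
    #: post-partum carryover: a foaling lowers next season's probability by
    #: carryover * (liability - 1), an open season raises it symmetrically,
    #: so careers are underdispersed relative to i.i.d. seasons (mares
    #: rarely foal six years running)
    foal_carryover: float = 0.35
    career_length_distribution: dict = field(
        default_factory=lambda: {3: 0.16, 4: 0.15, 5: 0.12, 6: 0.57}
    )
    abortion_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        for name in ("var_herd", "var_additive", "var_dominance", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_first_foaling_age3 <= 1.0:
            raise ValueError("p_first_foaling_age3 must be in [0, 1]")
        if not 0.0 <= self.abortion_fraction <= 1.0:
            raise ValueError("abortion_fraction must be in [0, 1]")
        probs = self.career_length_distribution
        if set(probs) - {3, 4, 5, 6}:
            raise ValueError("career lengths must be in {3, 4, 5, 6}")
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ValueError("career_length_distribution must be a probability distribution")
        if self.birth_year_range[0] >= self.birth_year_range[1]:
            raise ValueError("birth_year_range must be increasing")


@dataclass
class TrueValues:
    """Generating truth aligned to the pedigree."""

    breeding_value: pd.Series          # animal_id -> true BV (LFR units)
    dominance_deviation: pd.Series     # animal_id -> true dominance deviation
    herd_effect: dict                  # (eu_id, birth_year) -> herd effect
    inbreeding: pd.Series              # animal_id -> F
    recorded_mares: pd.DataFrame       # mare_id, birth_year, eu_id


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_pedigree(config: SimulationConfig) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate a multi-generation pedigree plus generating truth.

    Returns ``(pedigree, truth)``; the pedigree has columns ``animal_id``,
    ``sire_id``, ``dam_id``, ``birth_year``, ``sex`` ('M'/'F'), ancestors
    first, ids 1..n.  Recorded mares are a seeded sample of females with
    both parents known born from ``recording_from_year`` on, sized toward
    ``n_recorded_mares_target``.
    """
    config.validate()
    rng = _spawn(config.seed, 0)
    y0, y1 = config.birth_year_range
    G = config.n_generations
    interval = (y1 - y0) / G
    # only generations born inside the recording window yield recorded
    # mares (about half of each is female), so size cohorts accordingly
    n_era_gens = sum(
        1 for g in range(1, G + 1) if y0 + g * interval >= config.recording_from_year
    )
    n_per_gen = max(
        2, round(2.2 * config.n_recorded_mares_target / max(1, n_era_gens))
    )

    ids, sires, dams, years, sexes, gens = [], [], [], [], [], []
    next_id = 1
    n_male_founders = max(1, round(0.30 * config.n_founders))
    for i in range(config.n_founders):
        ids.append(next_id)
        sires.append(0)
        dams.append(0)
        years.append(int(y0 + rng.integers(0, max(1, round(interval)))))
        sexes.append("M" if i < n_male_founders else "F")
        gens.append(0)
        next_id += 1

    ids_a = np.array(ids)
    last_sire: dict[int, int] = {}
    for g in range(1, G + 1):
        gen_arr = np.array(gens)
        sex_arr = np.array(sexes)
        window = (gen_arr >= g - 3) & (gen_arr <= g - 1)
        males = ids_a[window & (sex_arr == "M")]
        females = ids_a[window & (sex_arr == "F")]
        if len(males) == 0 or len(females) == 0:
            raise ValueError("breeding pool exhausted; increase n_founders")
        k = min(config.sires_per_generation, len(males))
        sire_pool = rng.choice(males, size=k, replace=False)
        dam_order = rng.permutation(females)
        base_year = y0 + g * interval
        year_of = dict(zip(ids, years))
        for j in range(n_per_gen):
            dam = int(dam_order[j % len(dam_order)])
            prev = last_sire.get(dam)
            if prev is not None and rng.random() < config.repeat_mating_prob:
                sire = prev
            else:
                sire = int(sire_pool[rng.integers(0, len(sire_pool))])
            last_sire[dam] = sire
            ids.append(next_id)
            sires.append(int(sire))
            dams.append(int(dam))
            drawn = int(round(base_year + rng.integers(-1, 2)))
            years.append(max(drawn, year_of[int(sire)] + 1, year_of[int(dam)] + 1))
            sexes.append("M" if rng.random() < 0.5 else "F")
            gens.append(g)
            next_id += 1
        ids_a = np.array(ids)

    ped = pd.DataFrame(
        {
            "animal_id": ids,
            "sire_id": sires,
            "dam_id": dams,
            "birth_year": years,
            "sex": sexes,
        }
    )

    # recorded mares: seeded sample of eligible females in the era
    females = ped[(ped["sex"] == "F") & (ped["sire_id"] != 0) & (ped["dam_id"] != 0)]
    eligible = females[females["birth_year"] >= config.recording_from_year]
    n_rec = min(config.n_recorded_mares_target, len(eligible))
    pick = np.sort(rng.choice(eligible.index.to_numpy(), size=n_rec, replace=False))
    recorded_ids = ped.loc[pick, "animal_id"].to_numpy()

    # pedigree file = recorded mares plus their ancestor closure, the way
    # a studbook extract traces back from the animals under evaluation
    sire_of = dict(zip(ped["animal_id"], ped["sire_id"]))
    dam_of = dict(zip(ped["animal_id"], ped["dam_id"]))
    keep: set[int] = set()
    stack = [int(a) for a in recorded_ids]
    while stack:
        a = stack.pop()
        if a == 0 or a in keep:
            continue
        keep.add(a)
        stack.append(sire_of[a])
        stack.append(dam_of[a])
    ped = ped[ped["animal_id"].isin(keep)].reset_index(drop=True)

    A, ped_sorted = build_A(ped)
    Fs = pd.Series(np.diag(A) - 1.0, index=ped_sorted["animal_id"].to_numpy())
    D_rec = None
    if config.var_dominance > 0 and len(recorded_ids) > 1:
        D_rec = build_D(
            ped_sorted,
            A,
            ids=recorded_ids,
            index={a: i for i, a in enumerate(ped_sorted["animal_id"].to_numpy())},
        )
    del A

    # true breeding values, ancestors first
    bv = pd.Series(0.0, index=ped_sorted["animal_id"].to_numpy())
    sa = config.var_additive
    order_ids = ped_sorted["animal_id"].to_numpy()
    sire_map = dict(zip(ped["animal_id"], ped["sire_id"]))
    dam_map = dict(zip(ped["animal_id"], ped["dam_id"]))
    draws = rng.standard_normal(len(order_ids))
    for pos, a in enumerate(order_ids):
        s, d = sire_map[a], dam_map[a]
        mean = 0.0
        msv = 1.0  # Mendelian-sampling variance as a fraction of var_additive
        if s != 0 and d != 0:
            mean = 0.5 * (bv[s] + bv[d])
            msv = 0.5 * (1.0 - 0.5 * (Fs[s] + Fs[d]))
        elif s != 0 or d != 0:
            p = s if s != 0 else d
            mean = 0.5 * bv[p]
            msv = 0.75 - 0.25 * Fs[p]
        bv[a] = mean + draws[pos] * np.sqrt(msv * sa)

    # dominance deviations: recorded mares (the only animals whose
    # dominance ever reaches a phenotype) get draws with the pedigree
    # dominance covariance D, so the trait decomposition matches the
    # analysis model exactly; other animals get independent draws
    dom = pd.Series(
        rng.standard_normal(len(ped)) * np.sqrt(config.var_dominance),
        index=ped["animal_id"].to_numpy(),
    )
    if D_rec is not None:
        L = np.linalg.cholesky(D_rec + 1e-10 * np.eye(len(D_rec)))
        dom.loc[recorded_ids] = (
            L @ rng.standard_normal(len(D_rec))
        ) * np.sqrt(config.var_dominance)

    recorded = (
        ped[ped["animal_id"].isin(recorded_ids)][["animal_id", "birth_year"]]
        .rename(columns={"animal_id": "mare_id"})
        .sort_values("mare_id")
        .reset_index(drop=True)
    )
    recorded["eu_id"] = rng.integers(1, config.eu_count + 1, size=len(recorded))

    herd = {
        key: rng.standard_normal() * np.sqrt(config.var_herd)
        for key in sorted(
            {(int(e), int(b)) for e, b in zip(recorded["eu_id"], recorded["birth_year"])}
        )
    }

    truth = TrueValues(
        breeding_value=bv,
        dominance_deviation=dom,
        herd_effect=herd,
        inbreeding=Fs,
        recorded_mares=recorded,
    )
    return ped, truth


def _mare_level_draws(truth: TrueValues, config: SimulationConfig, stream: int):
    """Per-mare AF class, liability mean and residual, shared layout."""
    rng = _spawn(config.seed, stream)
    rec = truth.recorded_mares
    n = len(rec)
    af = np.where(rng.random(n) < config.p_first_foaling_age3, 3, 4)
    resid = rng.standard_normal(n) * np.sqrt(config.var_residual)
    F = truth.inbreeding.loc[rec["mare_id"]].to_numpy()
    herd = np.array(
        [truth.herd_effect[(int(e), int(b))] for e, b in zip(rec["eu_id"], rec["birth_year"])]
    )
    bv = truth.breeding_value.loc[rec["mare_id"]].to_numpy()
    dom = truth.dominance_deviation.loc[rec["mare_id"]].to_numpy()
    liab = (
        config.mean_lfr_liability
        + np.where(af == 4, config.af4_effect, 0.0)
        + config.inbreeding_depression_slope * F
        + herd
        + bv
        + dom
        + resid
    )
    return rng, rec, af, F, liab


def simulate_careers(
    pedigree: pd.DataFrame, truth: TrueValues, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate per-season reproductive events for every recorded mare.

    Returns a studbook table with columns ``mare_id``, ``event_year``,
    ``event_type`` ('F' foaling, 'A' abortion, 'O' open), ``age_months``,
    ``eu_id``.  Seasons are consecutive calendar years starting at age 3
    or 4; the per-season foaling probability is the mare's liability
    clamped to [0, 1]; non-foaling seasons split abortion/open at the
    configured fraction.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    rng, rec, af, _F, liab = _mare_level_draws(truth, config, stream=1)
    pi = np.clip(liab, 0.0, 1.0)
    lengths = np.array(sorted(config.career_length_distribution))
    probs = np.array([config.career_length_distribution[k] for k in lengths])
    L = rng.choice(lengths, size=len(rec), p=probs)

    rows = []
    for i, (mare, by, eu) in enumerate(
        zip(rec["mare_id"], rec["birth_year"], rec["eu_id"])
    ):
        mu, sd = AGE3_MONTHS if af[i] == 3 else AGE4_MONTHS
        lo, hi = (36, 47) if af[i] == 3 else (48, 59)
        age = float(np.clip(rng.normal(mu, sd), lo, hi))
        prev = None
        for s in range(int(L[i])):
            p = pi[i]
            if prev is not None:
                p = float(np.clip(pi[i] + config.foal_carryover * (pi[i] - prev), 0.0, 1.0))
            foal = rng.random() < p
            prev = float(foal)
            if foal:
                etype = "F"
            else:
                etype = "A" if rng.random() < config.abortion_fraction else "O"
            rows.append(
                {
                    "mare_id": int(mare),
                    "event_year": int(by + af[i] + s),
                    "event_type": etype,
                    "age_months": int(round(age)),
                    "eu_id": int(eu),
                }
            )
            age += 12 + rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15])
    return pd.DataFrame(rows)


def simulate_phenotypes(
    pedigree: pd.DataFrame, truth: TrueValues, config: SimulationConfig
) -> pd.DataFrame:
    """Direct Gaussian trait values on the LFR scale for recorded mares.

    The value is the liability itself (no clamping, no season sampling), so
    its decomposition is exactly the configured herd/additive/dominance/
    residual structure.  Columns: ``mare_id``, ``value``, ``af_class``,
    ``F``, ``eu_id``, ``birth_year``.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    _rng, rec, af, F, liab = _mare_level_draws(truth, config, stream=1)
    return pd.DataFrame(
        {
            "mare_id": rec["mare_id"].to_numpy(),
            "value": liab,
            "af_class": af,
            "F": F,
            "eu_id": rec["eu_id"].to_numpy(),
            "birth_year": rec["birth_year"].to_numpy(),
        }
    )


def truncate_careers(events: pd.DataFrame, k: int) -> pd.DataFrame:
    """First ``k`` seasons per mare; mares with fewer than ``k`` are dropped.

    ``k`` must be in {3, 4, 5}.  The input table is not modified.
    """
    if k not in (3, 4, 5):
        raise ValueError("k must be in {3, 4, 5}")
    ev = events.sort_values(["mare_id", "event_year"], kind="stable")
    grp = ev.groupby("mare_id", sort=False)
    counts = grp["event_year"].transform("size")
    rank = grp.cumcount()
    return ev[(counts >= k) & (rank < k)].reset_index(drop=True)


def write_studbook(events: pd.DataFrame, path) -> None:
    """Write the studbook CSV (mare_id,event_year,event_type,age_months,eu_id)."""
    events.to_csv(
        path,
        index=False,
        columns=["mare_id", "event_year", "event_type", "age_months", "eu_id"],
    )


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    """Write the pedigree CSV (animal_id,sire_id,dam_id,birth_year,sex)."""
    pedigree.to_csv(
        path,
        index=False,
        columns=["animal_id", "sire_id", "dam_id", "birth_year", "sex"],
    )
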