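"""Forward Wright-Fisher simulation of deleterious load under sexual,
clonal-apomictic and facultative reproduction.

Individuals are diploid with L biallelic loci carrying deleterious alleles;
fitness is multiplicative across loci, w = prod (1 - h*s)^het * (1 - s)^hom,
so the dominance coefficient h selects the model (0 = fully recessive,
0.5 = additive).  Reproduction each generation samples parents with
probability proportional to fitness; sexual offspring are formed from two
recombinant gametes (adjacent-locus recombination fraction r, 0.5 = free
recombination), clonal offspring copy the mother's diploid genotype, and a
facultatively apomictic population produces a fraction sigma of its offspring
sexually (residual sexuality).  New deleterious mutations arrive at rate U
per diploid genome per generation at uniformly chosen loci; loci fixed in a
population are folded into a constant fitness multiplier and recycled
(infinite-sites approximation at fixed memory).

The canonical demographic schedule mirrors a reproductive-mode-transition
experiment: a sexual burn-in, a split into an outcrossing population pO and
an apomixis-capable population pI, a single introgression pulse pO -> pI,
then a split of pI into pS (switching to sexual reproduction at the split)
and pA (remaining apomictic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_STATE = 200_000_000  # N*L guard (haplotype bytes) for desk-scale runs


class ExtinctionError(RuntimeError):
    def __init__(self, generation: int):
        super().__init__(f"all individuals have zero fitness at generation {generation}")
        self.generation = generation


@dataclass
class DFE:
    """Distribution of deleterious fitness effects: fixed s or gamma(shape, mean)."""

    kind: str = "fixed"  # "fixed" | "gamma"
    s: float = 0.05
    shape: float = 0.3
    mean: float = 0.05

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            out = np.full(n, self.s)
        elif self.kind == "gamma":
            out = rng.gamma(self.shape, self.mean / self.shape, size=n)
        else:
            raise ValueError(f"unknown DFE kind {self.kind!r}")
        if np.any((out < 0) | (out > 1)):
            out = np.clip(out, 0.0, 1.0)
        return out


@dataclass
class SimConfig:
    n: int = 500                 # individuals per population
    l: int = 2000                # deleterious-capable loci
    u: float = 0.2               # deleterious mutations per diploid genome per gen
    dfe: DFE = field(default_factory=DFE)
    h: float = 0.0               # dominance (0 recessive, 0.5 additive)
    recomb: float = 0.5          # adjacent-locus recombination fraction
    sigma: float = 0.05          # residual-sex fraction in apomictic mode
    pulse_fraction: float = 0.10
    burn_in_multiplier: float = 10.0
    burn_in: int | None = None   # explicit override of burn_in_multiplier * n
    gens_pI: int = 1000          # pO/pI split -> pulse -> pS/pA split span
    gens_post: int = 500         # generations simulated after the pS/pA split
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h", "sigma", "pulse_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if 2 * self.n * self.l > MAX_STATE:
            raise MemoryError(
                f"N*L = {self.n * self.l:.2e} exceeds the desk-scale state guard; "
                "reduce n or l (trajectory statistics do not need more)"
            )

    @property
    def burn_in_gens(self) -> int:
        return int(self.burn_in if self.burn_in is not None else
                   self.burn_in_multiplier * self.n)


@dataclass
class Population:
    """Haplotype state (n x 2 x L uint8) plus per-locus effects and the
    log-fitness constant contributed by fixed deleterious alleles."""

    hap: np.ndarray
    s: np.ndarray
    h: float
    fixed_log_w: float = 0.0

    @classmethod
    def founders(cls, cfg: SimConfig, rng: np.random.Generator) -> "Population":
        s = cfg.dfe.draw(cfg.l, rng)
        return cls(np.zeros((cfg.n, 2, cfg.l), dtype=np.uint8), s, cfg.h)

    def copy(self) -> "Population":
        return Population(self.hap.copy(), self.s, self.h, self.fixed_log_w)

    @property
    def n(self) -> int:
        return self.hap.shape[0]

    def dosage(self) -> np.ndarray:
        return self.hap.sum(axis=1)


def compute_fitness(dosage_row: np.ndarray, s: np.ndarray, h: float) -> float:
    """w = prod (1-h*s)^het * (1-s)^hom for one individual."""
    if np.any((s < 0) | (s > 1)):
        raise ValueError("selection coefficients must lie in [0, 1]")
    het = dosage_row == 1
    hom = dosage_row == 2
    return float(np.prod(1.0 - h * s[het]) * np.prod(1.0 - s[hom]))


def _log_fitness(pop: Population) -> np.ndarray:
    d = pop.dosage()
    with np.errstate(divide="ignore"):
        lhet = np.log1p(-pop.h * pop.s)
        lhom = np.log1p(-pop.s)
    return (d == 1).astype(np.float32) @ lhet.astype(np.float32) \
        + (d == 2).astype(np.float32) @ lhom.astype(np.float32)


def _fitness_weights(pop: Population, generation: int) -> np.ndarray:
    logw = _log_fitness(pop).astype(float)
    w = np.exp(logw - logw.max())
    tot = w.sum()
    if tot == 0 or not np.isfinite(tot):
        raise ExtinctionError(generation)
    return w / tot


def _gametes(hap: np.ndarray, parents: np.ndarray, recomb: float,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per row of ``parents`` (indices into hap)."""
    n, l = parents.size, hap.shape[2]
    flips = rng.random((n, l)) < recomb
    flips[:, 0] = rng.random(n) < 0.5
    which = np.logical_xor.accumulate(flips, axis=1)  # haplotype 0/1 along loci
    ph = hap[parents]  # n x 2 x L
    return np.where(which, ph[:, 1, :], ph[:, 0, :]).astype(np.uint8)


def _mutate(hap: np.ndarray, u: float, rng: np.random.Generator) -> None:
    n, _, l = hap.shape
    k = rng.poisson(u * n)
    if k:
        ind = rng.integers(0, n, size=k)
        hp = rng.integers(0, 2, size=k)
        loc = rng.integers(0, l, size=k)
        hap[ind, hp, loc] = 1


def _recycle_fixed(pop: Population) -> None:
    fixed = pop.hap.all(axis=(0, 1))
    if fixed.any():
        pop.fixed_log_w += float(np.sum(np.log1p(-pop.s[fixed])))
        pop.hap[:, :, fixed] = 0


def next_generation(pop: Population, mode, rng: np.random.Generator,
                    u: float, recomb: float = 0.5, n_offspring: int | None = None,
                    generation: int = 0,
                    donor: Population | None = None, pulse_f: float = 0.0) -> Population:
    """Produce the next generation.

    ``mode`` is ``"sexual"`` or ``("apomictic", sigma)``; apomictic offspring
    clone their mother with probability 1 - sigma and are produced sexually
    otherwise.  When ``donor``/``pulse_f`` are given, each offspring draws its
    parent(s) from the donor population with probability ``pulse_f`` (a
    one-generation introgression pulse).
    """
    if mode == "sexual":
        sigma = 1.0
    elif isinstance(mode, tuple) and mode[0] == "apomictic":
        sigma = float(mode[1])
    else:
        raise ValueError(f"unknown reproduction mode {mode!r}")
    n_off = pop.n if n_offspring is None else n_offspring
    w = _fitness_weights(pop, generation)
    w_donor = _fitness_weights(donor, generation) if donor is not None else None
    from_donor = (rng.random(n_off) < pulse_f) if donor is not None \
        else np.zeros(n_off, dtype=bool)
    sexual = rng.random(n_off) < sigma
    new_hap = np.empty((n_off, 2, pop.hap.shape[2]), dtype=np.uint8)

    def pick(source_pop, weights, count):
        return rng.choice(source_pop.n, size=count, p=weights)

    for use_donor in (False, True):
        src = donor if use_donor else pop
        srcw = w_donor if use_donor else w
        if src is None:
            continue
        grp = from_donor == use_donor
        # sexual offspring of this source
        gs = np.flatnonzero(grp & sexual)
        if gs.size:
            mothers = pick(src, srcw, gs.size)
            fathers = pick(src, srcw, gs.size)
            new_hap[gs, 0, :] = _gametes(src.hap, mothers, recomb, rng)
            new_hap[gs, 1, :] = _gametes(src.hap, fathers, recomb, rng)
        # clonal offspring
        gc = np.flatnonzero(grp & ~sexual)
        if gc.size:
            mothers = pick(src, srcw, gc.size)
            new_hap[gc] = src.hap[mothers]
    out = Population(new_hap, pop.s, pop.h, pop.fixed_log_w)
    _mutate(out.hap, u, rng)
    _recycle_fixed(out)
    return out


def apply_pulse(recipient: Population, donor: Population, f: float,
                rng: np.random.Generator, mode, u: float, recomb: float = 0.5,
                generation: int = 0) -> Population:
    """One generation in which offspring parents come from ``donor`` with
    probability f (realized donor ancestry ~ f)."""
    if not 0 <= f <= 1:
        raise ValueError("pulse fraction must be in [0, 1]")
    return next_generation(recipient, mode, rng, u=u, recomb=recomb,
                           generation=generation, donor=donor, pulse_f=f)


@dataclass
class FitnessTrajectory:
    """Per-generation summaries for one population of one replicate."""

    table: pd.DataFrame  # generation, mean_w, mean_het, mean_hom, seg_sites

    def w(self) -> np.ndarray:
        return self.table["mean_w"].to_numpy()


def _record(pop: Population, generation: int, rows: list) -> None:
    d = pop.dosage()
    logw = _log_fitness(pop).astype(float) + pop.fixed_log_w
    rows.append((
        generation,
        float(np.mean(np.exp(logw))),
        float(np.mean(np.sum(d == 1, axis=1))),
        float(np.mean(np.sum(d == 2, axis=1))),
        int(np.sum(d.any(axis=0))),
    ))


COLUMNS = ["generation", "mean_w", "mean_het", "mean_hom", "seg_sites"]


def run_forward(cfg: SimConfig) -> dict[str, FitnessTrajectory]:
    """Run the canonical schedule and return trajectories for pO, pI, pS, pA.

    Schedule: sexual burn-in (burn_in_gens) -> split pO/pI with pI switching
    to apomixis -> after gens_pI/2 a single pulse pO -> pI (pulse_fraction)
    -> at the end of gens_pI, pI splits into pS (sexual from then on) and pA
    (apomictic); both run a further gens_post generations.  All populations
    keep size n.  Deterministic given cfg (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    apo = ("apomictic", cfg.sigma)
    rows: dict[str, list] = {k: [] for k in ("pAnc", "pO", "pI", "pS", "pA")}
    pop = Population.founders(cfg, rng)
    gen = 0
    for _ in range(cfg.burn_in_gens):
        pop = next_generation(pop, "sexual", rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen)
        gen += 1
        _record(pop, gen, rows["pAnc"])
    p_o, p_i = pop.copy(), pop.copy()
    pulse_at = gen + cfg.gens_pI // 2
    split2_at = gen + cfg.gens_pI
    while gen < split2_at:
        donor = p_o if gen + 1 == pulse_at else None
        p_o = next_generation(p_o, "sexual", rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen)
        p_i = next_generation(p_i, apo, rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen, donor=donor,
                              pulse_f=cfg.pulse_fraction if donor else 0.0)
        gen += 1
        _record(p_o, gen, rows["pO"])
        _record(p_i, gen, rows["pI"])
    p_s, p_a = p_i.copy(), p_i.copy()
    # pS and pA continue the pI lineage; carry its history so that pre-switch
    # fitness is part of their trajectories
    rows["pS"] = list(rows["pI"])
    rows["pA"] = list(rows["pI"])
    for _ in range(cfg.gens_post):
        p_o = next_generation(p_o, "sexual", rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen)
        p_s = next_generation(p_s, "sexual", rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen)
        p_a = next_generation(p_a, apo, rng, u=cfg.u, recomb=cfg.recomb,
                              generation=gen)
        gen += 1
        _record(p_o, gen, rows["pO"])
        _record(p_s, gen, rows["pS"])
        _record(p_a, gen, rows["pA"])
    return {k: FitnessTrajectory(pd.DataFrame(v, columns=COLUMNS))
            for k, v in rows.items() if v}


@dataclass
class TransitionSummary:
    decline_pct: float
    minimum_generation: int
    recovery_generation: int | None


def summarize_transition(traj: FitnessTrajectory, switch_generation: int,
                         window: int, control: FitnessTrajectory | None = None,
                         eps: float = 0.005) -> TransitionSummary:
    """Fitness decline after a reproductive-mode switch.

    decline_pct = 100 * (w_pre - min w in the post-switch window) / w_pre,
    where w_pre is mean fitness in the generation before the switch.
    Recovery is the first post-minimum generation whose fitness is within
    ``eps`` (relative) of the control trajectory (or of w_pre without one).
    """
    t = traj.table
    gens = t["generation"].to_numpy()
    w = t["mean_w"].to_numpy()
    pre_idx = np.searchsorted(gens, switch_generation) - 1
    if pre_idx < 0 or switch_generation > gens[-1]:
        raise ValueError("switch generation outside trajectory")
    w_pre = w[pre_idx]
    post = (gens > switch_generation) & (gens <= switch_generation + window)
    if not post.any():
        raise ValueError("empty post-switch window")
    w_post = w[post]
    k_min = int(np.argmin(w_post))
    decline = 100.0 * (w_pre - w_post[k_min]) / w_pre
    gens_post = gens[post]
    rec = None
    for k in range(k_min, len(w_post)):
        if control is not None:
            ct = control.table
            ref = np.interp(gens_post[k], ct["generation"], ct["mean_w"])
        else:
            ref = w_pre
        if w_post[k] >= ref * (1.0 - eps):
            rec = int(gens_post[k])
            break
    return TransitionSummary(float(decline), int(gens_post[k_min]), rec)
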