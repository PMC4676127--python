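"""Two-population diploid cohorts under parametric bottleneck demographies.

The coalescent backend (msprime) is fixture plumbing only: the allele-
frequency-spectrum expectation used for inference lives in ``bkit.demog``
and is an independent Wright-Fisher grid engine.

Five scenarios, all sizes expressed as ratios of the diploid ancestral size
and times in generations before present:

* ``CONST`` — a single panmictic population (samples split arbitrarily).
* ``IM``   — split into two populations with symmetric migration.
* ``BIM``  — ancestral bottleneck, then a split.
* ``SBR``  — split, then a bottleneck and recovery in each population.
* ``ISB``  — ancestral growth, split, then an independent bottleneck in
  each population lasting to the present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import msprime
import numpy as np

from bkit.io import VariantTable

MODEL_IDS = ("IM", "BIM", "SBR", "ISB", "CONST")

# epoch_params keys each model requires (sizes nu_* are ratios of the
# ancestral diploid size; times t_* in generations; m per lineage per gen)
_REQUIRED = {
    "CONST": (),
    "IM": ("nu1", "nu2", "t_split", "m"),
    "BIM": ("nu_b", "t_b", "nu1", "nu2", "t_split"),
    "SBR": ("t_split", "nu1_b", "nu2_b", "t_b", "nu1_r", "nu2_r", "t_r"),
    "ISB": ("nu_g", "t_g", "t_split", "nu1_b", "nu2_b", "t_b1", "t_b2"),
}


@dataclass
class DemographyScenario:
    model_id: str
    ancestral_size: int                      # diploid individuals
    epoch_params: Mapping[str, float]
    mutation_rate: float                     # per site, interpreted per rate_units
    generation_time: float = 3.0             # years per generation
    sequence_length: int = 1_000_000
    sample_sizes: tuple[int, int] = (8, 6)   # haploid counts per population
    rate_units: str = "generation"           # "generation" or "year"

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        missing = [k for k in _REQUIRED[self.model_id] if k not in self.epoch_params]
        if missing:
            raise ValueError(f"epoch_params missing {missing} for {self.model_id}")
        if self.ancestral_size <= 0:
            raise ValueError("ancestral_size must be positive")
        for key, val in self.epoch_params.items():
            if key.startswith("nu") and val <= 0:
                raise ValueError(f"epoch_params[{key!r}] must be > 0")
            if key.startswith("t_") and val < 0:
                raise ValueError(f"epoch_params[{key!r}] must be >= 0")
            if key == "m" and val < 0:
                raise ValueError("epoch_params['m'] must be >= 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample_sizes must each be >= 2")
        if any(n % 2 for n in self.sample_sizes):
            raise ValueError("haploid sample_sizes must be even (diploid cohort)")
        self._check_time_order()

    def _check_time_order(self) -> None:
        p = self.epoch_params
        if self.model_id == "SBR" and p["t_r"] + p["t_b"] > p["t_split"]:
            raise ValueError("epoch_params: t_r + t_b must not exceed t_split")
        if self.model_id == "ISB":
            if max(p["t_b1"], p["t_b2"]) > p["t_split"]:
                raise ValueError("epoch_params: bottleneck onsets must precede t_split")

    @property
    def mu_per_generation(self) -> float:
        if self.rate_units == "generation":
            return self.mutation_rate
        if self.rate_units == "year":
            return self.mutation_rate * self.generation_time
        raise ValueError(f"rate_units must be 'generation' or 'year', got {self.rate_units!r}")

    @property
    def theta_per_site(self) -> float:
        """4 * N_ref * mu, the scaled per-site mutation rate."""
        return 4.0 * self.ancestral_size * self.mu_per_generation

    def scaled_params(self) -> dict[str, float]:
        """Model parameters in diffusion units (times / 2 N_ref generations,
        migration as 2 N_ref m), matching ``bkit.demog`` conventions."""
        two_n = 2.0 * self.ancestral_size
        out: dict[str, float] = {}
        for key, val in self.epoch_params.items():
            if key.startswith("t_"):
                out["tau" + key[1:]] = val / two_n
            elif key == "m":
                out["M"] = two_n * val
            else:
                out[key] = float(val)
        return out

    def to_demography(self) -> msprime.Demography:
        N = float(self.ancestral_size)
        p = self.epoch_params
        d = msprime.Demography()
        if self.model_id == "CONST":
            d.add_population(name="pop0", initial_size=N)
            return d
        d.add_population(name="anc", initial_size=N)
        if self.model_id == "IM":
            d.add_population(name="pop1", initial_size=p["nu1"] * N)
            d.add_population(name="pop2", initial_size=p["nu2"] * N)
            d.set_symmetric_migration_rate(["pop1", "pop2"], p["m"])
            d.add_population_split(time=p["t_split"], derived=["pop1", "pop2"],
                                   ancestral="anc")
        elif self.model_id == "BIM":
            d.add_population(name="pop1", initial_size=p["nu1"] * N)
            d.add_population(name="pop2", initial_size=p["nu2"] * N)
            d.add_population_split(time=p["t_split"], derived=["pop1", "pop2"],
                                   ancestral="anc")
            # ancestral bottleneck for t_b generations just before the split
            d.add_population_parameters_change(time=p["t_split"], population="anc",
                                               initial_size=p["nu_b"] * N)
            d.add_population_parameters_change(time=p["t_split"] + p["t_b"],
                                               population="anc", initial_size=N)
        elif self.model_id == "SBR":
            d.add_population(name="pop1", initial_size=p["nu1_r"] * N)
            d.add_population(name="pop2", initial_size=p["nu2_r"] * N)
            d.add_population_parameters_change(time=p["t_r"], population="pop1",
                                               initial_size=p["nu1_b"] * N)
            d.add_population_parameters_change(time=p["t_r"], population="pop2",
                                               initial_size=p["nu2_b"] * N)
            d.add_population_parameters_change(time=p["t_r"] + p["t_b"],
                                               population="pop1", initial_size=N)
            d.add_population_parameters_change(time=p["t_r"] + p["t_b"],
                                               population="pop2", initial_size=N)
            d.add_population_split(time=p["t_split"], derived=["pop1", "pop2"],
                                   ancestral="anc")
        elif self.model_id == "ISB":
            d.add_population(name="pop1", initial_size=p["nu1_b"] * N)
            d.add_population(name="pop2", initial_size=p["nu2_b"] * N)
            d.add_population_parameters_change(time=p["t_b1"], population="pop1",
                                               initial_size=p["nu_g"] * N)
            d.add_population_parameters_change(time=p["t_b2"], population="pop2",
                                               initial_size=p["nu_g"] * N)
            d.add_population_split(time=p["t_split"], derived=["pop1", "pop2"],
                                   ancestral="anc")
            d.add_population_parameters_change(time=p["t_split"], population="anc",
                                               initial_size=p["nu_g"] * N)
            d.add_population_parameters_change(time=p["t_split"] + p["t_g"],
                                               population="anc", initial_size=N)
        d.sort_events()
        return d


@dataclass
class SyntheticCohort:
    """Simulated variant table plus the truth record that produced it."""

    variants: VariantTable
    pop_of_sample: dict[str, int]            # sample name -> 0/1
    scenario: DemographyScenario
    seed: int
    scaffold: str = "scaf1"

    def samples_in_pop(self, pop: int) -> list[int]:
        return [i for i, s in enumerate(self.variants.samples)
                if self.pop_of_sample[s] == pop]


def simulate_two_pop_cohort(scenario: DemographyScenario, seed: int,
                            depth_mean: float = 15.0) -> SyntheticCohort:
    """Coalescent-simulate diploid genotypes for both populations.

    Ancestral alleles are known exactly (the simulated ancestral state is
    written as REF and recorded in the ancestral sidecar).  Per-sample depth
    is Poisson(depth_mean), independent across sites.  Deterministic given
    ``seed``.
    """
    n1, n2 = scenario.sample_sizes
    if scenario.model_id == "CONST":
        sample_sets = {"pop0": (n1 + n2) // 2}
    else:
        sample_sets = {"pop1": n1 // 2, "pop2": n2 // 2}
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=scenario.to_demography(),
        sequence_length=scenario.sequence_length,
        recombination_rate=1e-8,
        random_seed=max(1, seed % (2 ** 31)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=scenario.mu_per_generation,
        model=msprime.BinaryMutationModel(),
        random_seed=max(1, (seed + 7919) % (2 ** 31)),
    )

    positions, refs, alts, gts = [], [], [], []
    n_dip = (n1 + n2) // 2
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue  # recurrent hits collapse to non-biallelic; skip (rare)
        g = var.genotypes.reshape(n_dip, 2)
        if g.max() == 0 or g.min() == 1:
            continue  # monomorphic in the sample
        positions.append(int(var.site.position) + 1)
        refs.append("A" if var.site.ancestral_state == "0" else "C")
        alts.append("C" if var.site.ancestral_state == "0" else "A")
        gts.append(g.copy())
    # de-duplicate integer positions (discrete genome collisions)
    keep = []
    seen: set[int] = set()
    for i, p in enumerate(positions):
        if p not in seen:
            seen.add(p)
            keep.append(i)
    positions = [positions[i] for i in keep]

    rng = np.random.default_rng(seed)
    n_sites = len(positions)
    depth = rng.poisson(depth_mean, size=(n_sites, n_dip)).astype(np.int32)

    samples = [f"ind{i}" for i in range(n_dip)]
    pop_of_sample = {s: (0 if i < n1 // 2 else 1) for i, s in enumerate(samples)}
    table = VariantTable(
        samples=samples,
        scaffold=np.array(["scaf1"] * n_sites, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array([refs[i] for i in keep], dtype=object),
        alt=np.array([alts[i] for i in keep], dtype=object),
        gt=(np.stack([gts[i] for i in keep]).astype(np.int8)
            if n_sites else np.zeros((0, n_dip, 2), dtype=np.int8)),
        depth=depth,
        ancestral=np.array([refs[i] for i in keep], dtype=object),
    )
    return SyntheticCohort(variants=table, pop_of_sample=pop_of_sample,
                           scenario=scenario, seed=seed)
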