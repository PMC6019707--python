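"""Synthetic trio cohorts with configurable typing-error processes.

The generator draws founder (parent) genotypes independently per locus
under Hardy-Weinberg equilibrium from a configured allele-frequency
vector, transmits one uniformly chosen allele from each parent to the
child, and then perturbs the truth with an error model per synthetic
typing method:

1. *homozygote inflation* — with probability ``eta`` a heterozygous pair
   {a, b} is replaced by {a, a} (a chosen uniformly), mimicking typers
   that spuriously call homozygous loci;
2. *miscalls* — each allele slot is independently replaced with
   probability ``epsilon``; with probability ``sigma`` the replacement is
   a different allele from the same 2-digit serotype group (serotype-
   preserving miscall), otherwise a uniformly chosen different pool
   allele;
3. *resolution truncation* — the observed call is reduced to the method's
   output resolution (4 or 8 digits).

Randomness is drawn from one stream per (seed, method) keyed by sample
and locus, so outputs are deterministic regardless of iteration order.
The default rates (epsilon=0.05, sigma=0.5, eta=0.02) are illustrative:
no quantitative error rates are available for the failure modes they
emulate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .cohort_io import (
    GenotypeCall,
    SampleRecord,
    TrioCohort,
    write_genotype_table,
    write_pedigree,
)
from .nomenclature import AlleleName, format_allele, parse_allele, reduce_allele

__all__ = [
    "LocusPool",
    "ErrorModel",
    "SimulationConfig",
    "ErrorEvent",
    "SimulatedCohort",
    "default_pool",
    "dirichlet_pool",
    "simulate_truth_cohort",
    "apply_typing_error",
    "simulate_benchmark",
    "load_config",
    "write_simulated_cohort",
]

ALL_ROLES = frozenset({"father", "mother", "child"})


@dataclass(frozen=True)
class LocusPool:
    """Allele pool for one locus: 8-digit alleles with a frequency vector."""

    locus: str
    alleles: tuple[AlleleName, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.frequencies):
            raise ValueError(f"pool for {self.locus}: alleles/frequencies length mismatch")
        if not self.alleles:
            raise ValueError(f"pool for {self.locus} is empty")
        total = float(sum(self.frequencies))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool for {self.locus}: frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.frequencies):
            raise ValueError(f"pool for {self.locus}: negative frequency")
        for a in self.alleles:
            if a.gene != self.locus:
                raise ValueError(f"allele {format_allele(a)} not at locus {self.locus}")


@dataclass(frozen=True)
class ErrorModel:
    """Error process for one synthetic typing method."""

    method: str
    miscall_rate: float = 0.05              # epsilon
    serotype_preserving_fraction: float = 0.5  # sigma
    homozygote_inflation_rate: float = 0.02    # eta
    output_resolution: int = 4
    roles: frozenset[str] = ALL_ROLES
    novel_replacement: bool = False

    def __post_init__(self) -> None:
        for name in ("miscall_rate", "serotype_preserving_fraction", "homozygote_inflation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.output_resolution not in (4, 8):
            raise ValueError(f"output_resolution must be 4 or 8, got {self.output_resolution}")
        if not isinstance(self.roles, frozenset):
            object.__setattr__(self, "roles", frozenset(self.roles))
        bad = self.roles - ALL_ROLES
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")


@dataclass
class SimulationConfig:
    """Cohort size, per-locus allele pools, error models, and seed."""

    n_families: int = 50
    pools: dict[str, LocusPool] = field(default_factory=dict)
    error_models: list[ErrorModel] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not self.pools:
            rng = np.random.default_rng(self.seed)
            self.pools = {l: dirichlet_pool(l, rng=rng) for l in ("A", "B", "C")}
        labels = [m.method for m in self.error_models]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate method labels in error models: {labels}")
        for model in self.error_models:
            for pool in self.pools.values():
                if model.miscall_rate > 0 and not model.novel_replacement and len(pool.alleles) < 2:
                    raise ValueError(
                        f"pool for {pool.locus} has <2 alleles; miscalls cannot "
                        "draw a distinct replacement"
                    )

    @property
    def loci(self) -> list[str]:
        return list(self.pools)


def default_pool(locus: str, frequencies: Sequence[float] | None = None) -> LocusPool:
    """A 12-allele pool with serotype structure.

    Four 2-digit groups; each group holds a pair of 8-digit alleles that
    share their 4-digit protein but differ in the non-coding field (so
    reduction can merge them), plus one distinct protein.  Uniform
    frequencies unless given.
    """
    alleles = []
    for g in range(1, 5):
        grp = f"{g:02d}"
        alleles += [
            AlleleName(locus, (grp, "01", "01", "01")),
            AlleleName(locus, (grp, "01", "01", "02")),
            AlleleName(locus, (grp, "02", "01", "01")),
        ]
    if frequencies is None:
        frequencies = [1.0 / len(alleles)] * len(alleles)
    return LocusPool(locus, tuple(alleles), tuple(float(f) for f in frequencies))


def dirichlet_pool(
    locus: str,
    n_alleles: int = 12,
    concentration: float = 1.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LocusPool:
    """The default pool shape with a symmetric-Dirichlet frequency draw."""
    if rng is None:
        rng = np.random.default_rng(seed)
    base = default_pool(locus)
    if n_alleles > len(base.alleles):
        raise ValueError(f"default pool shape holds at most {len(base.alleles)} alleles")
    alleles = base.alleles[:n_alleles]
    freqs = rng.dirichlet([concentration] * len(alleles))
    return LocusPool(locus, alleles, tuple(freqs.tolist()))


def _rng(seed: int, method: str, sample_id: str, locus: str) -> np.random.Generator:
    """Deterministic per-call stream keyed by (seed, method, sample, locus)."""
    key = [zlib.crc32(s.encode()) for s in (method, sample_id, locus)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *key]))


def simulate_truth_cohort(config: SimulationConfig) -> TrioCohort:
    """Hardy-Weinberg founders plus Mendelian transmission to children.

    Parents draw two independent alleles from the locus frequency vector;
    each child receives one uniformly chosen allele from each parent.
    The truth cohort has descent accuracy 1 by construction.
    """
    samples: list[SampleRecord] = []
    cohort = TrioCohort(loci=config.loci)
    for i in range(config.n_families):
        fam = f"fam{i:04d}"
        recs = {role: SampleRecord(f"{fam}-{role}", fam, role) for role in ("father", "mother", "child")}
        samples.extend(recs.values())
        for locus, pool in config.pools.items():
            parent_pairs = {}
            for role in ("father", "mother"):
                rng = _rng(config.seed, "truth", recs[role].sample_id, locus)
                idx = rng.choice(len(pool.alleles), size=2, p=np.asarray(pool.frequencies))
                parent_pairs[role] = (pool.alleles[idx[0]], pool.alleles[idx[1]])
                cohort.add_call(
                    GenotypeCall(recs[role].sample_id, locus, "truth", parent_pairs[role])
                )
            rng = _rng(config.seed, "truth", recs["child"].sample_id, locus)
            child_pair = (
                parent_pairs["mother"][rng.integers(2)],
                parent_pairs["father"][rng.integers(2)],
            )
            cohort.add_call(GenotypeCall(recs["child"].sample_id, locus, "truth", child_pair))
    cohort.samples = samples
    return cohort


@dataclass(frozen=True)
class ErrorEvent:
    """Provenance of one perturbation applied to a truth call."""

    sample_id: str
    locus: str
    kind: str  # homozygote_inflation | miscall_serotype | miscall_random | miscall_novel
    slot: int | None = None


def _novel_allele(locus: str, rng: np.random.Generator) -> AlleleName:
    # allele-group 99 never appears in generated pools, so the replacement
    # cannot be explained by any pool-derived truth genotype
    return AlleleName(
        locus,
        ("99", f"{int(rng.integers(0, 100)):02d}", f"{int(rng.integers(0, 100)):02d}", "01"),
    )


def apply_typing_error(
    truth: TrioCohort,
    model: ErrorModel,
    config: SimulationConfig,
) -> tuple[TrioCohort, list[ErrorEvent]]:
    """Perturb a truth cohort into one synthetic method's observed calls.

    Per individual x locus (for roles the model targets): homozygote
    inflation first, then per-slot miscalls, then reduction to the output
    resolution.  Calls for untargeted roles are copied (reduced) verbatim.
    """
    observed = TrioCohort(samples=list(truth.samples), loci=list(truth.loci))
    events: list[ErrorEvent] = []
    roles = {s.sample_id: s.role for s in truth.samples}
    for (method, sample_id, locus), call in truth.typings.items():
        if method != "truth":
            continue
        pair = list(call.alleles)
        if roles[sample_id] in model.roles:
            rng = _rng(config.seed, model.method, sample_id, locus)
            if pair[0] != pair[1] and rng.random() < model.homozygote_inflation_rate:
                keep = pair[int(rng.integers(2))]
                pair = [keep, keep]
                events.append(ErrorEvent(sample_id, locus, "homozygote_inflation"))
            pool = config.pools[locus]
            for slot in range(2):
                if rng.random() >= model.miscall_rate:
                    continue
                current = pair[slot]
                if model.novel_replacement:
                    pair[slot] = _novel_allele(locus, rng)
                    events.append(ErrorEvent(sample_id, locus, "miscall_novel", slot))
                    continue
                preserve = rng.random() < model.serotype_preserving_fraction
                if preserve:
                    candidates = [
                        a
                        for a in pool.alleles
                        if a != current and a.fields[0] == current.fields[0]
                    ]
                    kind = "miscall_serotype"
                    if not candidates:
                        candidates = [a for a in pool.alleles if a != current]
                        kind = "miscall_random"
                else:
                    candidates = [a for a in pool.alleles if a != current]
                    kind = "miscall_random"
                pair[slot] = candidates[int(rng.integers(len(candidates)))]
                events.append(ErrorEvent(sample_id, locus, kind, slot))
        reduced = tuple(reduce_allele(a, model.output_resolution) for a in pair)
        observed.add_call(GenotypeCall(sample_id, locus, model.method, reduced))
    return observed, events


@dataclass
class SimulatedCohort:
    """Ground truth plus error-perturbed observations per synthetic method."""

    truth: TrioCohort
    observed: dict[str, TrioCohort]
    provenance: dict[str, list[ErrorEvent]]
    config: SimulationConfig

    def merged(self) -> TrioCohort:
        """One cohort holding truth and all observed methods together."""
        merged = TrioCohort(samples=list(self.truth.samples), loci=list(self.truth.loci))
        for call in self.truth.typings.values():
            merged.add_call(call)
        for obs in self.observed.values():
            for call in obs.typings.values():
                merged.add_call(call)
        return merged


def simulate_benchmark(config: SimulationConfig) -> SimulatedCohort:
    """Simulate truth and every configured synthetic method's typings."""
    truth = simulate_truth_cohort(config)
    observed: dict[str, TrioCohort] = {}
    provenance: dict[str, list[ErrorEvent]] = {}
    for model in config.error_models:
        obs, events = apply_typing_error(truth, model, config)
        observed[model.method] = obs
        provenance[model.method] = events
    return SimulatedCohort(truth=truth, observed=observed, provenance=provenance, config=config)


def write_simulated_cohort(sim: SimulatedCohort, out_dir: str | Path) -> list[Path]:
    """Write pedigree and per-method genotype TSVs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    ped = out_dir / "pedigree.tsv"
    write_pedigree(sim.truth.samples, ped)
    written.append(ped)
    for label, cohort in [("truth", sim.truth), *sim.observed.items()]:
        path = out_dir / f"genotypes_{label}.tsv"
        calls = sorted(
            cohort.typings.values(), key=lambda c: (c.sample_id, c.locus)
        )
        write_genotype_table(calls, path)
        written.append(path)
    return written


def load_config(path: str | Path, seed: int | None = None) -> SimulationConfig:
    """Load a simulation config from YAML.

    Schema::

        n_families: 50
        seed: 0
        pools:                      # optional; Dirichlet defaults otherwise
          A:
            alleles: [A*01:01:01:01, ...]
            frequencies: [0.3, ...]
        methods:
          - method: typerA
            miscall_rate: 0.05
            serotype_preserving_fraction: 0.5
            homozygote_inflation_rate: 0.02
            output_resolution: 4
            roles: [father, mother, child]
            novel_replacement: false
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pools = {}
    for locus, spec in (raw.get("pools") or {}).items():
        alleles = tuple(parse_allele(a) for a in spec["alleles"])
        pools[locus] = LocusPool(locus, alleles, tuple(float(f) for f in spec["frequencies"]))
    models = [
        ErrorModel(
            method=m["method"],
            miscall_rate=float(m.get("miscall_rate", 0.05)),
            serotype_preserving_fraction=float(m.get("serotype_preserving_fraction", 0.5)),
            homozygote_inflation_rate=float(m.get("homozygote_inflation_rate", 0.02)),
            output_resolution=int(m.get("output_resolution", 4)),
            roles=frozenset(m.get("roles", sorted(ALL_ROLES))),
            novel_replacement=bool(m.get("novel_replacement", False)),
        )
        for m in raw.get("methods", [])
    ]
    return SimulationConfig(
        n_families=int(raw.get("n_families", 50)),
        pools=pools,
        error_models=models,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
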