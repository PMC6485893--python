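"""Synthetic MSAP study generator with known ground truth.

Emulates the design of a clonal-propagation methylation study: three
genotypes, each with field-maintained and micropropagated groups of 24
ramets, fingerprinted with two selective-primer combinations of ~240 loci.
Each methylation-susceptible locus (MSL) draws per-genotype, per-group
state distributions around a global state mixture; differentially
methylated (DM) loci shift the micropropagated distribution toward an
alternative state.  Non-methylated loci (NML) emit concordant band
presence/absence at a genotype-specific frequency.  States map to
(HpaII, MspI) band pairs through the inverse of the state-calling rule,
then symmetric per-cell scoring errors and missingness are injected.

Every draw flows from one seed, so a fixed seed reproduces the matrices
and the truth bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_profiles import PairedProfile, SampleRecord, ScoreMatrix
from .meth_states import STATES, band_pair

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate", "effect_grid"]

_DEFAULT_GENOTYPES = ("Bohye", "Ogyefo", "Otoo")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated study: 3 genotypes x 2 propagation systems
    x 24 ramets (144 samples), 240 loci per primer combination, ~70% MSL,
    state mixture (I, II, III, IV) = (21.5, 11.2, 19.3, 48.2)%, and a 3%
    per-cell scoring-error rate (the middle of the 2-9% reproducibility
    range typical of MSAP screens).
    """

    n_genotypes: int = 3
    genotype_names: tuple = _DEFAULT_GENOTYPES
    n_per_group: int = 24
    n_loci: int = 240
    primers: tuple = ("E", "I")
    msl_fraction: float = 0.7
    state_mixture: tuple = (0.215, 0.112, 0.193, 0.482)  # I, II, III, IV
    dm_fraction: float = 0.15
    dm_fraction_by_genotype: Mapping[str, float] | None = None
    dm_effect: float = 0.6
    nml_freq_beta: tuple = (8.0, 1.0)
    genetic_polymorphism: float = 0.0  # presence-freq shift of NML in micro group
    error_rate: float = 0.03
    missing_rate: float = 0.0
    dirichlet_concentration: float = 50.0
    n_duplicates: int = 0  # technical duplicates per genotype x group
    seed: int | None = None

    def __post_init__(self) -> None:
        # printed study percentages can sum to ~100.2 from rounding; accept
        # anything close to 1 and renormalise at draw time
        if abs(sum(self.state_mixture) - 1.0) > 0.01:
            raise ValueError("state_mixture must sum to ~1")
        for name in ("msl_fraction", "dm_fraction", "dm_effect",
                     "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def genotypes(self) -> tuple:
        if len(self.genotype_names) >= self.n_genotypes:
            return tuple(self.genotype_names[: self.n_genotypes])
        return tuple(
            list(self.genotype_names)
            + [f"G{i + 1}" for i in range(len(self.genotype_names), self.n_genotypes)]
        )


@dataclass
class SimTruth:
    """Ground truth of one simulation, keyed by primer."""

    locus_class: dict                 # primer -> Series (MSL/NML per locus)
    dm_loci: dict                     # primer -> {genotype: [locus ids]}
    group_state_dist: dict            # primer -> {(genotype, group): DataFrame loci x states}
    states: dict                      # primer -> pre-error state DataFrame (samples x loci)


@dataclass
class SimResult:
    profiles: dict                    # primer -> PairedProfile
    metadata: list
    truth: SimTruth
    config: SimConfig


def _shift_distribution(base: np.ndarray, target: int, effect: float) -> np.ndarray:
    """Shift ``effect`` total-variation distance of mass toward ``target``.

    The mixing weight is solved so the total-variation distance between the
    input and output distributions equals ``effect``; when the target state
    already holds too much mass for that to be feasible the shift saturates
    at a point mass (with a warning), the closest achievable distribution.
    """
    headroom = 1.0 - base[target]
    if headroom <= effect:
        logger.warning(
            "dm shift toward state %d infeasible at effect %.2f "
            "(headroom %.2f); saturating", target, effect, headroom
        )
        out = np.zeros_like(base)
        out[target] = 1.0
        return out
    eps = effect / headroom
    out = (1.0 - eps) * base
    out[target] += eps
    return out / out.sum()


def simulate(config: SimConfig) -> SimResult:
    """Generate paired profiles, metadata and ground truth for one study."""
    rng = np.random.default_rng(config.seed)
    genotypes = config.genotypes
    groups = ("field", "micro")

    metadata: list[SampleRecord] = []
    for geno in genotypes:
        for prop in groups:
            for k in range(config.n_per_group):
                metadata.append(
                    SampleRecord(
                        sample_id=f"{geno}_{prop}_{k + 1:02d}",
                        genotype=geno,
                        propagation=prop,
                        block=f"B{k % 3 + 1}",
                    )
                )
    core_ids = [r.sample_id for r in metadata]
    dup_sources: list[SampleRecord] = []
    if config.n_duplicates:
        for geno in genotypes:
            for prop in groups:
                for k in range(config.n_duplicates):
                    src = f"{geno}_{prop}_{k + 1:02d}"
                    dup_sources.append(
                        SampleRecord(
                            sample_id=f"{src}_dup",
                            genotype=geno,
                            propagation=prop,
                            block=f"B{k % 3 + 1}",
                            replicate_of=src,
                        )
                    )
    metadata = metadata + dup_sources
    all_ids = [r.sample_id for r in metadata]

    mixture = np.asarray(config.state_mixture, dtype=float)
    mixture = mixture / mixture.sum()
    conc = config.dirichlet_concentration
    dm_frac = dict(config.dm_fraction_by_genotype or {})

    locus_class: dict[str, pd.Series] = {}
    dm_loci: dict[str, dict] = {}
    group_dist: dict[str, dict] = {}
    truth_states: dict[str, pd.DataFrame] = {}
    profiles: dict[str, PairedProfile] = {}

    for primer in config.primers:
        loci = [f"{primer}{i + 1:03d}" for i in range(config.n_loci)]
        n_msl = int(round(config.msl_fraction * config.n_loci))
        msl_idx = np.sort(rng.choice(config.n_loci, size=n_msl, replace=False))
        is_msl = np.zeros(config.n_loci, dtype=bool)
        is_msl[msl_idx] = True
        locus_class[primer] = pd.Series(
            np.where(is_msl, "MSL", "NML"), index=loci, name="class"
        )

        dm_loci[primer] = {}
        group_dist[primer] = {}
        # pre-error state codes 0..3 = I..IV for every core+duplicate sample
        state_code = np.empty((len(core_ids), config.n_loci), dtype=np.int8)

        row0 = 0
        for geno in genotypes:
            frac = dm_frac.get(geno, config.dm_fraction)
            n_dm = int(round(frac * n_msl))
            dm_pos = np.sort(rng.choice(n_msl, size=n_dm, replace=False)) if n_dm else np.array([], int)
            dm_ids = [loci[msl_idx[j]] for j in dm_pos]
            dm_loci[primer][geno] = dm_ids

            base = rng.dirichlet(conc * mixture, size=n_msl)
            # treatment shifts mass toward an alternative state: one drawn
            # among the states that are NOT the locus's dominant state, so a
            # methylation change is actually visible against the baseline
            draw = rng.integers(0, 3, size=n_msl)
            argmax = base.argmax(axis=1)
            alt = np.array([[s for s in range(4) if s != a] for a in argmax])
            targets = alt[np.arange(n_msl), draw]
            dist = {"field": base.copy(), "micro": base.copy()}
            for j in dm_pos:
                dist["micro"][j] = _shift_distribution(
                    base[j].copy(), int(targets[j]), config.dm_effect
                )
            # NML: genotype-specific presence frequency, shared by both groups
            # unless a genetic propagation effect is requested
            a, b = config.nml_freq_beta
            nml_freq = rng.beta(a, b, size=config.n_loci - n_msl)
            nml_freq_micro = np.clip(
                nml_freq + config.genetic_polymorphism * rng.choice([-1.0, 1.0], size=nml_freq.size),
                0.0, 1.0,
            ) if config.genetic_polymorphism else nml_freq

            for gi, grp in enumerate(groups):
                group_dist[primer][(geno, grp)] = pd.DataFrame(
                    dist[grp], index=[loci[i] for i in msl_idx], columns=list(STATES)
                )
                n = config.n_per_group
                # MSL: categorical draw via inverse-CDF on per-locus mixtures
                cum = np.cumsum(dist[grp], axis=1)
                u = rng.random((n, n_msl))
                codes_msl = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
                # NML: concordant bands; state I = present, state IV = absent
                f = nml_freq if grp == "field" else nml_freq_micro
                present = rng.random((n, f.size)) < f[None, :]
                codes_nml = np.where(present, 0, 3).astype(np.int8)
                block = np.empty((n, config.n_loci), dtype=np.int8)
                block[:, is_msl] = codes_msl
                block[:, ~is_msl] = codes_nml
                state_code[row0: row0 + n] = block
                row0 += n

        # technical duplicates copy the source sample's pre-error states
        full_code = state_code
        if dup_sources:
            src_rows = [core_ids.index(r.replicate_of) for r in dup_sources]
            full_code = np.vstack([state_code, state_code[src_rows]])

        state_names = np.array(list(STATES), dtype=object)
        truth_states[primer] = pd.DataFrame(
            state_names[full_code], index=all_ids, columns=loci
        )

        # states -> band pairs, then independent per-cell error and missingness
        pairs = np.array([band_pair(s) for s in STATES], dtype=np.int8)
        h = pairs[full_code, 0].astype(float)
        m = pairs[full_code, 1].astype(float)
        for bands in (h, m):
            if config.error_rate > 0:
                flip = rng.random(bands.shape) < config.error_rate
                bands[flip] = 1.0 - bands[flip]
            if config.missing_rate > 0:
                bands[rng.random(bands.shape) < config.missing_rate] = np.nan
        profiles[primer] = PairedProfile(
            hpa=ScoreMatrix("HpaII", primer, pd.DataFrame(h, index=all_ids, columns=loci)),
            msp=ScoreMatrix("MspI", primer, pd.DataFrame(m, index=all_ids, columns=loci)),
            primer=primer,
        )

    truth = SimTruth(
        locus_class=locus_class,
        dm_loci=dm_loci,
        group_state_dist=group_dist,
        states=truth_states,
    )
    return SimResult(profiles=profiles, metadata=metadata, truth=truth, config=config)


def _child_seed(seed: int | None, *key: int) -> int:
    entropy = [0 if seed is None else int(seed), *key]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def effect_grid(
    config: SimConfig,
    dm_effects: Sequence[float],
    n_reps: int = 5,
    seed: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Power/recovery table across a grid of micropropagation effect sizes.

    For each effect size, ``n_reps`` studies are simulated and summarised:
    mean Phi_ST over MSL recodes, mean Phi_PT over band matrices, detection
    power of seeded DM loci at the given FDR, and the observed false
    discovery proportion.  AMOVA permutations are skipped (only the Phi
    point estimates are needed here).
    """
    from .amova import amova_two_group, pairwise_distance
    from .diffmeth import test_all_msl
    from .io_profiles import metadata_frame
    from .meth_states import call_states, partition_loci, recode_msl_binary

    rows = []
    for ei, effect in enumerate(dm_effects):
        phist, phipt, powers, fdrs = [], [], [], []
        for rep in range(n_reps):
            cfg = dataclasses.replace(
                config, dm_effect=float(effect), seed=_child_seed(seed, ei, rep)
            )
            sim = simulate(cfg)
            meta = metadata_frame(sim.metadata)
            for primer, profile in sim.profiles.items():
                states = call_states(profile)
                part = partition_loci(states, error_rate=cfg.error_rate)
                for geno in cfg.genotypes:
                    ids = meta.index[(meta.genotype == geno) & meta.replicate_of.isna()]
                    grp = meta.loc[ids, "propagation"].to_dict()
                    sub_states = type(states)(states.values.loc[ids], primer)
                    msl_bin = recode_msl_binary(sub_states, part)
                    D = pairwise_distance(msl_bin, "hamming_sq")
                    phist.append(amova_two_group(D, grp, n_perm=0).phi)
                    Dpt = pairwise_distance(profile.hpa.values.loc[ids], "hamming_sq")
                    phipt.append(amova_two_group(Dpt, grp, n_perm=0).phi)
                    dm = test_all_msl(sub_states, part, grp, fdr=fdr)
                    seeded = set(sim.truth.dm_loci[primer][geno])
                    called = set(dm.loc[dm.significant, "locus_id"])
                    if seeded:
                        powers.append(len(called & seeded) / len(seeded))
                    fdrs.append(len(called - seeded) / max(len(called), 1))
        rows.append(
            {
                "dm_effect": float(effect),
                "mean_phist_msl": float(np.mean(phist)),
                "mean_phipt": float(np.mean(phipt)),
                "power": float(np.mean(powers)) if powers else float("nan"),
                "observed_fdr": float(np.mean(fdrs)),
            }
        )
    return pd.DataFrame(rows)
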