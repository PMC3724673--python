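"""Synthetic genome cohorts with known compositional structure.

The generator emulates the statistical structure the analysis assumes in a
real prokaryotic corpus, without any sequence download:

* a nested phylum / genus / species taxonomy,
* a wide genomic %AT gradient (default 25–86 %AT, the observed prokaryotic
  range) that is cluster-correlated within taxa — the random-slope
  structure the hierarchical models are built for,
* a tunable codon-level bias with an analytically known Kullback-Leibler
  divergence from the factorised (zeroth-order) null.

Codon distributions are built by exponentially tilting the factorised
distribution implied by a target %AT with a fixed weight vector over the 64
codons: ``p_c ∝ p0_c · exp(beta · w_c)``.  Tilting preserves support (KL
stays finite), gives smooth KL growth in ``beta``, and — because the weights
are not separable across codon positions — induces genuine between-position
dependence.  ``beta = 0`` recovers the factorised null exactly.

The per-genome ``beta`` can be linked to %AT (decreasing by default), which
reproduces the observed KL-decreases-with-AT pattern by construction, and is
jittered hierarchically (a shared phylum factor plus a genome factor) so
that responses carry the cluster effects the mixed models must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import BiasMetrics, CODONS, CompositionProfile, profile_from_counts, relative_entropy_kl
from .errors import ContractViolation
from .seqio import CdsSet

#: fixed exponential-tilt weights over the 64 codons (lexicographic order).
#: An arbitrary but frozen draw of standard normals: non-separable across
#: codon positions, so tilting creates between-position dependence; frozen
#: so analytic KL values are stable regression-test constants.
TILT_WEIGHTS = np.array([
    -0.387, 1.377, 0.883, 1.612, -0.433, -0.151, -0.195, 0.126,
    -0.716, 2.059, 2.392, -1.307, -1.455, -1.294, -2.085, -0.115,
    1.524, -0.599, 1.781, -1.399, -0.449, 0.188, 0.9, 1.828,
    -1.619, 0.347, -0.322, -1.515, 0.65, 0.41, 0.214, 2.992,
    0.426, 0.149, -2.176, 1.07, 0.972, -0.478, 0.791, -0.311,
    0.329, -0.353, 0.227, 0.402, -0.051, -0.736, -0.846, -2.776,
    0.01, -1.233, 0.769, 0.482, -1.624, 0.002, -0.753, 0.755,
    0.4, 0.361, -1.16, -0.585, -1.201, 1.729, 1.242, -0.488,
])

_CODON_STRS = np.array(CODONS)


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the corpus the analysis targets: a 600-genome cohort
    (30 phyla x 5 genera x 4 species, one genome per species), %AT spanning
    0.25–0.86, genus/species %AT deviations of a few percent, and a codon
    bias that decays with %AT so relative entropy falls as genomes become
    AT-rich.
    """

    n_phyla: int = 30
    genera_per_phylum: int = 5
    species_per_genus: int = 4
    at_range: tuple[float, float] = (0.25, 0.86)
    sigma_phylum: float = 0.02     # SD of extra phylum-mean %AT deviation
    sigma_genus: float = 0.02      # SD of genus %AT deviation
    sigma_species: float = 0.01    # SD of species %AT deviation
    bias_beta: float = 0.4         # tilt strength; 0 = factorised null
    bias_link: str | None = "at"   # "at": beta decays linearly with %AT; None: constant
    sigma_beta_phylum: float = 0.15  # SD of shared log-normal beta jitter per phylum
    sigma_beta_genome: float = 0.10  # SD of per-genome log-normal beta jitter
    n_codons_per_genome: int = 20000
    coding_fraction_range: tuple[float, float] = (0.75, 0.95)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.at_range
        if not (0.0 < lo < hi < 1.0):
            raise ContractViolation("at_range must satisfy 0 < low < high < 1")
        for name in ("sigma_phylum", "sigma_genus", "sigma_species",
                     "sigma_beta_phylum", "sigma_beta_genome"):
            if getattr(self, name) < 0:
                raise ContractViolation(f"{name} must be >= 0")
        if self.bias_beta < 0:
            raise ContractViolation("bias_beta must be >= 0")
        if min(self.n_phyla, self.genera_per_phylum, self.species_per_genus) < 1:
            raise ContractViolation("taxonomy counts must be >= 1")
        if self.n_codons_per_genome < 1:
            raise ContractViolation("n_codons_per_genome must be >= 1")

    @property
    def n_genomes(self) -> int:
        return self.n_phyla * self.genera_per_phylum * self.species_per_genus


@dataclass
class SimulatedCohort:
    """A cohort plus its generative ground truth."""

    config: CohortConfig
    taxonomy: pd.DataFrame            # genome_id, phylum, genus, species, strain
    truth: pd.DataFrame               # per-genome true %AT, beta, analytic KL, sizes
    distributions: np.ndarray         # n_genomes x 64 true codon distributions
    codon_counts: np.ndarray          # n_genomes x 64 sampled codon counts
    cds_sets: list[CdsSet] | None = None

    def profiles(self) -> tuple[list[CompositionProfile], list[BiasMetrics]]:
        profs, mets = [], []
        for i, gid in enumerate(self.truth["genome_id"]):
            p, m = profile_from_counts(
                gid, self.codon_counts[i], genome_size=int(self.truth["genome_size"].iloc[i])
            )
            profs.append(p)
            mets.append(m)
        return profs, mets


def simulate_taxonomy(config: CohortConfig, rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the nested taxonomy and per-genome true %AT.

    Phylum %AT means are uniform on ``at_range`` (plus an optional normal
    deviation of SD ``sigma_phylum``); genus and species effects are
    zero-mean normal deviations with the configured SDs.  The result is
    clipped to (0.05, 0.95).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.at_range
    rows = []
    ats = []
    g = 0
    for p in range(config.n_phyla):
        phylum = f"P{p + 1:02d}"
        at_p = rng.uniform(lo, hi) + rng.normal(0.0, config.sigma_phylum)
        for q in range(config.genera_per_phylum):
            genus = f"G{q + 1:02d}"
            at_g = at_p + rng.normal(0.0, config.sigma_genus)
            for s in range(config.species_per_genus):
                g += 1
                gid = f"SIM{g:05d}"
                at = float(np.clip(at_g + rng.normal(0.0, config.sigma_species), 0.05, 0.95))
                rows.append(
                    {"genome_id": gid, "phylum": phylum, "genus": genus,
                     "species": f"S{s + 1:02d}", "strain": gid}
                )
                ats.append(at)
    taxonomy = pd.DataFrame(rows)
    return taxonomy, pd.Series(ats, index=taxonomy["genome_id"], name="at_true")


def build_codon_distribution(at_target: float, bias_beta: float) -> tuple[np.ndarray, float]:
    """Exponentially tilted codon distribution and its analytic KL (bits).

    Starts from the factorised distribution with marginals
    A = T = at/2, C = G = (1-at)/2, tilts by ``exp(beta * w)`` with the
    fixed weight vector, renormalises, and returns the KL divergence of the
    result from the factorised null of its *own* nucleotide marginals.
    """
    if not (0.0 < at_target < 1.0):
        raise ContractViolation("at_target must lie strictly between 0 and 1")
    if bias_beta < 0:
        raise ContractViolation("bias_beta must be >= 0")
    marg = np.array([at_target / 2, (1 - at_target) / 2, (1 - at_target) / 2, at_target / 2])
    p0 = np.einsum("i,j,k->ijk", marg, marg, marg).ravel()
    p = p0 * np.exp(bias_beta * TILT_WEIGHTS)
    p /= p.sum()
    from .composition import CODON_BASE_COUNTS

    own_marg = p @ CODON_BASE_COUNTS / 3.0
    kl = relative_entropy_kl(p, own_marg)
    return p, kl


def effective_beta(config: CohortConfig, at: float) -> float:
    """The bias strength before jitter: constant, or decaying linearly in
    %AT from ``bias_beta`` at the low end of ``at_range`` to 0 at the high
    end (clipped outside)."""
    if config.bias_link is None:
        return config.bias_beta
    if config.bias_link == "at":
        lo, hi = config.at_range
        return config.bias_beta * float(np.clip((hi - at) / (hi - lo), 0.0, 1.0))
    raise ContractViolation(f"unknown bias_link {config.bias_link!r}")


def simulate_genome(
    distribution: np.ndarray,
    n_codons: int,
    rng: np.random.Generator,
    genome_id: str = "sim",
    pack: bool = True,
    cds_codons: int = 300,
) -> CdsSet:
    """Draw ``n_codons`` i.i.d. codons and pack them into CDS records.

    With ``pack=True`` each CDS of ~``cds_codons`` codons is prefixed with
    ATG and terminated with TAA for I/O realism (those codons slightly
    perturb frequencies); with ``pack=False`` the draw becomes a single CDS
    with exact multinomial frequencies.
    """
    distribution = np.asarray(distribution, dtype=float)
    if n_codons < 1:
        raise ContractViolation("n_codons must be >= 1")
    if distribution.shape != (64,) or np.any(distribution < 0) or abs(distribution.sum() - 1) > 1e-9:
        raise ContractViolation("distribution must be a 64-vector of proportions")
    draws = rng.choice(64, size=n_codons, p=distribution)
    codons = _CODON_STRS[draws]
    cds_set = CdsSet(genome_id=genome_id, replicon_id=genome_id)
    if not pack:
        cds_set.cds.append((f"{genome_id}_cds1", "".join(codons)))
        return cds_set
    for j, start in enumerate(range(0, n_codons, cds_codons)):
        body = "".join(codons[start : start + cds_codons])
        cds_set.cds.append((f"{genome_id}_cds{j + 1}", "ATG" + body + "TAA"))
    return cds_set


def simulate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    sequences: bool = False,
    pack: bool = True,
) -> SimulatedCohort:
    """Simulate a full cohort: taxonomy, true distributions, codon counts and
    (optionally) packed CDS sequences.

    Codon counts are multinomial draws from each genome's true distribution;
    when ``sequences=True`` the same draws are materialised as CDS records
    (so the FASTA route and the counts route agree up to the optional
    packing codons).  Genome size is 3 x n_codons divided by a drawn coding
    fraction, emulating non-coding content.
    """
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    taxonomy, at_true = simulate_taxonomy(config, rng)
    n = config.n_genomes
    lo_cf, hi_cf = config.coding_fraction_range

    phylum_jit = {
        ph: rng.normal(0.0, config.sigma_beta_phylum)
        for ph in taxonomy["phylum"].unique()
    }
    dists = np.empty((n, 64))
    counts = np.empty((n, 64), dtype=np.int64)
    rows = []
    cds_sets: list[CdsSet] | None = [] if sequences else None
    for i, rec in enumerate(taxonomy.itertuples(index=False)):
        at = float(at_true.iloc[i])
        beta = effective_beta(config, at) * float(
            np.exp(phylum_jit[rec.phylum] + rng.normal(0.0, config.sigma_beta_genome))
        )
        dist, kl = build_codon_distribution(at, beta)
        dists[i] = dist
        coding_fraction = rng.uniform(lo_cf, hi_cf)
        genome_size = int(round(3 * config.n_codons_per_genome / coding_fraction))
        if sequences:
            cds = simulate_genome(
                dist, config.n_codons_per_genome, rng, genome_id=rec.genome_id, pack=pack
            )
            cds_sets.append(cds)
            from .composition import count_codons

            counts[i], _ = count_codons(cds)
        else:
            counts[i] = rng.multinomial(config.n_codons_per_genome, dist)
        rows.append(
            {"genome_id": rec.genome_id, "at_true": at, "beta": beta,
             "kl_analytic": kl, "n_codons": config.n_codons_per_genome,
             "genome_size": genome_size, "coding_fraction": coding_fraction}
        )
    truth = pd.DataFrame(rows)
    return SimulatedCohort(
        config=config, taxonomy=taxonomy, truth=truth,
        distributions=dists, codon_counts=counts, cds_sets=cds_sets,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the same formats the ingest module reads:
    one CDS multi-FASTA per genome, a taxonomy TSV, and a truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort.cds_sets is None:
        raise ContractViolation("cohort was simulated without sequences")
    fasta_dir = out_dir / "fasta"
    fasta_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for cds_set in cohort.cds_sets:
        path = fasta_dir / f"{cds_set.genome_id}.fasta"
        with open(path, "w") as fh:
            for cds_id, seq in cds_set.cds:
                fh.write(f">{cds_id}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        paths[cds_set.genome_id] = path
    cohort.taxonomy.to_csv(out_dir / "taxonomy.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.12g")
    return paths
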