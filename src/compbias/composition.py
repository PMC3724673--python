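"""Per-genome composition profiles and the three bias statistics.

For each genome (or replicon) we estimate

* nucleotide frequencies ``F(X)`` over (A, C, G, T),
* codon frequencies ``F(XYZ)`` over the 64 codons (non-overlapping in-frame
  triplets of the provided ORFs, stop codons included),
* amino-acid frequencies over the 20 standard residues of the translated
  proteome,

and from these three statistics:

* **AAUB** (amino acid usage bias): the empirical standard deviation of the
  20 amino-acid frequencies,
* **CUB** (codon usage bias): the same statistic over the 64 codon
  frequencies,
* **KL**: the Kullback-Leibler divergence (in bits) of the observed codon
  frequencies from the zeroth-order null ``F(X)F(Y)F(Z)`` implied by the
  genome's own nucleotide frequencies.

A high AAUB/CUB means a few categories dominate; KL = 0 means codons look
like independent draws of single bases.  These are distinct from codon
adaptation indices (CAI and relatives), which are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation, EmptyInputError, InfiniteDivergenceError
from .seqio import CdsSet, ProteinSet, _codon_to_aa, translate_set

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: the 64 codons in lexicographic order over (A, C, G, T)
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
#: the 20 standard amino acids in alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i

_AA_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_a)] = _i

#: codon index -> count of each base within the codon (64 x 4)
CODON_BASE_COUNTS = np.zeros((64, 4), dtype=np.int64)
for _c, _codon in enumerate(CODONS):
    for _b in _codon:
        CODON_BASE_COUNTS[_c, BASES.index(_b)] += 1

#: codon index -> amino-acid index in AMINO_ACIDS, or -1 for stop codons
#: (NCBI translation table 11)
CODON_AA_INDEX = np.array(
    [
        AMINO_ACIDS.index(aa) if aa != "*" else -1
        for aa in (_codon_to_aa(11)[c] for c in CODONS)
    ],
    dtype=np.int64,
)


@dataclass
class CompositionProfile:
    genome_id: str
    nuc_freq: np.ndarray        # 4-vector over (A, C, G, T)
    codon_freq: np.ndarray      # 64-vector, lexicographic codon order
    aa_freq: np.ndarray         # 20-vector, alphabetical one-letter order
    at_fraction: float
    n_codons: int
    n_residues: int
    genome_size: int


@dataclass
class BiasMetrics:
    genome_id: str
    aaub: float
    cub: float
    kl: float  # bits


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_codons(cds_set: CdsSet) -> tuple[np.ndarray, int]:
    """Count non-overlapping in-frame triplets over all CDS of a genome.

    Returns (counts over the 64 codons, number of skipped triplets).  Triplets
    containing N are skipped rather than redistributed.
    """
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    for seq in cds_set.sequences():
        idx = _encode(seq).reshape(-1, 3)
        ok = (idx >= 0).all(axis=1)
        skipped += int((~ok).sum())
        codes = idx[ok] @ np.array([16, 4, 1])
        counts += np.bincount(codes, minlength=64)
    return counts, skipped


def codon_frequencies(cds_set: CdsSet) -> tuple[np.ndarray, int]:
    """Codon proportions over all CDS of a genome, plus the triplet count."""
    if not cds_set.cds:
        raise EmptyInputError("empty CdsSet")
    counts, skipped = count_codons(cds_set)
    total = int(counts.sum())
    if total == 0:
        raise EmptyInputError("no countable triplets (all contained N)")
    if skipped:
        logger.debug("%s: skipped %d triplets containing N", cds_set.genome_id, skipped)
    return counts / total, total


def nucleotide_frequencies(cds_set: CdsSet, whole_sequence: str | None = None) -> np.ndarray:
    """Base proportions (A, C, G, T), N excluded.

    By default computed over the positions of the counted codons (which
    guarantees a finite KL against the factorised null); pass a
    whole-replicon sequence to use genomic marginals instead.
    """
    if whole_sequence is not None:
        idx = _encode(whole_sequence)
        counts = np.bincount(idx[idx >= 0], minlength=4).astype(float)
    else:
        codon_counts, _ = count_codons(cds_set)
        counts = (codon_counts @ CODON_BASE_COUNTS).astype(float)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("no countable bases")
    return counts / total


def amino_acid_frequencies(proteins: ProteinSet) -> tuple[np.ndarray, int]:
    """Residue proportions pooled over all proteins of a genome."""
    if not proteins.proteins:
        raise EmptyInputError("empty ProteinSet")
    pooled = "".join(proteins.proteins)
    idx = _AA_INDEX[np.frombuffer(pooled.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        raise ContractViolation("protein sequences contain non-standard symbols")
    counts = np.bincount(idx, minlength=20)
    total = int(counts.sum())
    if total == 0:
        raise EmptyInputError("zero residues")
    return counts / total, total


def at_content(sequence: str) -> float:
    """(A + T) / (A + C + G + T); N excluded from the denominator."""
    idx = _encode(sequence)
    counts = np.bincount(idx[idx >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("no unambiguous bases")
    return float((counts[0] + counts[3]) / total)


def usage_bias(freqs: np.ndarray) -> float:
    """Empirical standard deviation of a proportion vector.

    With k categories summing to one the mean is 1/k, so this is
    ``sqrt(sum((x_i - 1/k)^2) / (k - 1))``; k = 20 gives AAUB and k = 64
    gives CUB.  The sample (k-1) denominator is used; AAUB/CUB enter all
    downstream analyses only up to ordering and linear scale.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.size
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ContractViolation("frequency vector must sum to 1")
    mu = 1.0 / k
    return float(np.sqrt(((freqs - mu) ** 2).sum() / (k - 1)))


def relative_entropy_kl(
    codon_freq: np.ndarray, nuc_freq: np.ndarray, base: str = "bits"
) -> float:
    """Kullback-Leibler divergence of codon frequencies from the factorised
    (zeroth-order) null ``F(X)F(Y)F(Z)``.

    Terms with zero observed frequency contribute nothing; a positive
    observed frequency over a zero-probability null codon is an infinite
    divergence (cannot occur when the marginals come from the same counted
    codons).  Result in bits by default, nats with ``base="nats"``.
    """
    p = np.asarray(codon_freq, dtype=float)
    q4 = np.asarray(nuc_freq, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or abs(q4.sum() - 1.0) > 1e-9:
        raise ContractViolation("both vectors must be proportions summing to 1")
    expected = np.einsum("i,j,k->ijk", q4, q4, q4).ravel()
    pos = p > 0
    if np.any(expected[pos] == 0):
        raise InfiniteDivergenceError(
            "observed codon has zero probability under the factorised null"
        )
    log = np.log2 if base == "bits" else np.log
    kl = float(np.sum(p[pos] * log(p[pos] / expected[pos])))
    if -1e-12 < kl < 0:
        kl = 0.0
    return kl


def aa_frequencies_from_codon_counts(codon_counts: np.ndarray) -> tuple[np.ndarray, int]:
    """Amino-acid proportions implied by codon counts under translation
    table 11 (stop codons dropped).

    Equivalent to translating the CDS and pooling residues whenever the
    codons came from in-frame ORFs.
    """
    counts = np.zeros(20, dtype=np.int64)
    sense = CODON_AA_INDEX >= 0
    np.add.at(counts, CODON_AA_INDEX[sense], codon_counts[sense])
    total = int(counts.sum())
    if total == 0:
        raise EmptyInputError("zero residues implied by codon counts")
    return counts / total, total


def profile_from_counts(
    genome_id: str,
    codon_counts: np.ndarray,
    genome_size: int | None = None,
) -> tuple[CompositionProfile, BiasMetrics]:
    """Build profile + bias metrics directly from a 64-vector of codon counts.

    This is the fast path used for simulated genomes; it is arithmetically
    identical to counting codons in the packed CDS records.
    """
    total = int(codon_counts.sum())
    if total == 0:
        raise EmptyInputError("zero codon counts")
    codon_freq = codon_counts / total
    base_counts = (codon_counts @ CODON_BASE_COUNTS).astype(float)
    nuc_freq = base_counts / base_counts.sum()
    aa_freq, n_res = aa_frequencies_from_codon_counts(codon_counts)
    at = float(nuc_freq[0] + nuc_freq[3])
    profile = CompositionProfile(
        genome_id=genome_id,
        nuc_freq=nuc_freq,
        codon_freq=codon_freq,
        aa_freq=aa_freq,
        at_fraction=at,
        n_codons=total,
        n_residues=n_res,
        genome_size=genome_size if genome_size is not None else 3 * total,
    )
    metrics = BiasMetrics(
        genome_id=genome_id,
        aaub=usage_bias(aa_freq),
        cub=usage_bias(codon_freq),
        kl=relative_entropy_kl(codon_freq, nuc_freq),
    )
    return profile, metrics


def profile_genome(
    cds_set: CdsSet,
    whole_sequence: str | None = None,
    genetic_code: int = 11,
    marginals: str = "cds",
) -> tuple[CompositionProfile, BiasMetrics]:
    """Full composition profile and bias statistics for one genome.

    ``marginals`` selects the nucleotide frequencies used in the KL null:
    ``"cds"`` (default) uses the bases of the counted codons, which keeps the
    divergence finite by construction; ``"genome"`` uses the whole-replicon
    sequence (requires ``whole_sequence``).  %AT is taken from
    ``whole_sequence`` when provided, else from the CDS.
    """
    codon_freq, n_codons = codon_frequencies(cds_set)
    if marginals == "genome":
        if whole_sequence is None:
            raise ContractViolation('marginals="genome" requires whole_sequence')
        nuc_freq = nucleotide_frequencies(cds_set, whole_sequence)
    elif marginals == "cds":
        nuc_freq = nucleotide_frequencies(cds_set)
    else:
        raise ContractViolation(f"unknown marginals mode {marginals!r}")
    proteins = translate_set(cds_set, code=genetic_code)
    aa_freq, n_residues = amino_acid_frequencies(proteins)
    if whole_sequence is not None:
        at = at_content(whole_sequence)
        genome_size = len(whole_sequence)
    else:
        at = float(nuc_freq[0] + nuc_freq[3]) if marginals == "cds" else at_content(
            "".join(cds_set.sequences())
        )
        genome_size = sum(len(s) for s in cds_set.sequences())
    profile = CompositionProfile(
        genome_id=cds_set.genome_id,
        nuc_freq=nuc_freq,
        codon_freq=codon_freq,
        aa_freq=aa_freq,
        at_fraction=at,
        n_codons=n_codons,
        n_residues=n_residues,
        genome_size=genome_size,
    )
    metrics = BiasMetrics(
        genome_id=cds_set.genome_id,
        aaub=usage_bias(aa_freq),
        cub=usage_bias(codon_freq),
        kl=relative_entropy_kl(codon_freq, nuc_freq),
    )
    return profile, metrics
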