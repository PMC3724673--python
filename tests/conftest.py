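"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
pairwise enumeration) so they stay independent of the vectorised code paths
they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from compbias.seqio import CdsSet

settings.register_profile("suite", derandomize=True, database=None, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sd_bruteforce(values) -> float:
    """Two-pass sample standard deviation with explicit loops."""
    n = len(values)
    mean = sum(values) / n
    acc = 0.0
    for v in values:
        acc += (v - mean) ** 2
    return math.sqrt(acc / (n - 1))


def kl_bruteforce(codon_freq, nuc_freq) -> float:
    """Term-by-term KL sum over all 64 codons, in bits."""
    bases = "ACGT"
    total = 0.0
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            for k, c in enumerate(bases):
                p = codon_freq[16 * i + 4 * j + k]
                if p > 0:
                    q = nuc_freq[i] * nuc_freq[j] * nuc_freq[k]
                    total += p * math.log2(p / q)
    return total


def count_codons_naive(cds_set: CdsSet) -> dict[str, int]:
    """Per-record triplet recount with string slicing."""
    counts: dict[str, int] = {}
    for _, seq in cds_set.cds:
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def reverse_complement_naive(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def complete_linkage_bruteforce(X: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration; returns the cophenetic distance matrix."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return coph


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "cds.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by pipeline-level tests."""
    import compbias as cb
    from compbias.pipeline import profiles_to_frame

    cohort = cb.simulate_cohort(
        cb.CohortConfig(
            n_phyla=9, genera_per_phylum=3, species_per_genus=3,
            n_codons_per_genome=3000, seed=11,
        )
    )
    profs, mets = cohort.profiles()
    return cohort, profiles_to_frame(profs, mets)


def grouped_regression_data(
    seed: int,
    m_groups: int = 30,
    n_per: int = 10,
    intercept_sd: float = 0.0,
    slope_sd: float = 0.0,
    noise_sd: float = 0.2,
    fixed_linear: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate grouped data y = sin(2*pi*x) + fixed_linear*z + u_g + v_g*x + eps
    with a one-level taxonomy (all genomes directly under phyla)."""
    rng = np.random.default_rng(seed)
    n = m_groups * n_per
    g = np.repeat(np.arange(m_groups), n_per)
    x = rng.uniform(0, 1, n)
    z = rng.uniform(0, 1, n)
    u = rng.normal(0, intercept_sd, m_groups)
    v = rng.normal(0, slope_sd, m_groups)
    y = np.sin(2 * np.pi * x) + fixed_linear * z + u[g] + v[g] * x
    y = y + rng.normal(0, noise_sd, n)
    ph = [f"P{i:02d}" for i in g]
    data = pd.DataFrame(
        {"genome_id": [f"g{i}" for i in range(n)], "y": y, "x": x, "z": z}
    )
    taxonomy = pd.DataFrame(
        {"genome_id": data["genome_id"], "phylum": ph, "genus": ph,
         "species": ph, "strain": data["genome_id"]}
    )
    return data, taxonomy
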