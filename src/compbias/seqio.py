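"""Reading coding sequences and taxonomy tables; translation; TSV output.

Coding sequences arrive either as a nucleotide multi-FASTA (one record per
CDS/ORF) or as a GenBank flat file with annotated CDS features.  All
sequences are normalised to uppercase DNA over {A, C, G, T, N}; records whose
length is not a positive multiple of 3 are dropped (truncating would shift
the reading frame silently), and the drop count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import ContractViolation, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

_DNA_KEEP = set("ACGTN")
# any IUPAC ambiguity code other than N is collapsed to N
_AMBIG = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


@dataclass
class CdsSet:
    """The coding sequences of one replicon/genome."""

    genome_id: str
    replicon_id: str
    cds: list[tuple[str, str]] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:  # number of retained CDS
        return len(self.cds)

    def sequences(self) -> Iterable[str]:
        return (seq for _, seq in self.cds)


@dataclass(frozen=True)
class TaxonomyAssignment:
    genome_id: str
    phylum: str
    genus: str
    species: str
    strain: str


@dataclass
class ProteinSet:
    genome_id: str
    proteins: list[str] = field(default_factory=list)


def _normalise_dna(seq: str) -> str:
    s = seq.upper().replace("U", "T").translate(_AMBIG)
    if not set(s) <= _DNA_KEEP:
        bad = sorted(set(s) - _DNA_KEEP)
        raise FormatError(f"non-nucleotide characters in sequence: {bad}")
    return s


def _add_record(cds_set: CdsSet, cds_id: str, seq: str) -> None:
    seq = _normalise_dna(seq)
    if len(seq) >= 3 and len(seq) % 3 == 0:
        cds_set.cds.append((cds_id, seq))
    else:
        cds_set.n_skipped += 1


def read_cds_fasta(path: str | Path, genome_id: str, replicon_id: str | None = None) -> CdsSet:
    """Read one genome's CDS records from a nucleotide multi-FASTA.

    Lowercase input is uppercased, U is mapped to T, and records whose
    length is not a positive multiple of 3 are skipped (count logged).
    """
    path = Path(path)
    cds_set = CdsSet(genome_id=genome_id, replicon_id=replicon_id or genome_id)
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate CDS id {rec.id!r} in {path}")
        seen.add(rec.id)
        _add_record(cds_set, rec.id, str(rec.seq))
    if cds_set.n_skipped:
        logger.warning(
            "%s: skipped %d CDS with length not a positive multiple of 3",
            path, cds_set.n_skipped,
        )
    if not cds_set.cds:
        raise EmptyInputError(f"no usable CDS records in {path}")
    return cds_set


def extract_cds_from_genbank(path: str | Path, genome_id: str | None = None) -> CdsSet:
    """Extract CDS features from a GenBank flat file.

    Complement-strand features are reverse-complemented and joined locations
    concatenated in feature order (Biopython's feature extraction); the same
    length filter as :func:`read_cds_fasta` applies.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path} contains no GenBank records")
    rec0 = records[0]
    cds_set = CdsSet(genome_id=genome_id or rec0.id, replicon_id=rec0.id)
    counter = 0
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            cds_id = feat.qualifiers.get("locus_tag", [f"cds_{counter:05d}"])[0]
            seq = str(feat.location.extract(rec.seq))
            _add_record(cds_set, cds_id, seq)
    if counter == 0:
        raise EmptyInputError(f"no CDS features in {path}")
    if cds_set.n_skipped:
        logger.warning("%s: skipped %d CDS (length filter)", path, cds_set.n_skipped)
    if not cds_set.cds:
        raise EmptyInputError(f"no usable CDS features in {path}")
    return cds_set


def _codon_to_aa(code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_cds(cds_sequence: str, code: int = 11) -> str:
    """Translate an in-frame CDS with the given NCBI genetic code (default 11,
    bacterial/archaeal).

    A terminal stop codon is dropped; internal stops and codons containing N
    yield no symbol (the position is skipped and logged at debug level).
    """
    seq = _normalise_dna(cds_sequence)
    if len(seq) % 3 != 0:
        raise ContractViolation("CDS length must be divisible by 3")
    mapping = _codon_to_aa(code)
    out: list[str] = []
    n_codons = len(seq) // 3
    skipped = 0
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            skipped += 1
            continue
        aa = mapping[codon]
        if aa == "*":
            if i != n_codons - 1:
                skipped += 1
            continue
        out.append(aa)
    if skipped:
        logger.debug("translate_cds: skipped %d internal stop/ambiguous codons", skipped)
    return "".join(out)


def translate_set(cds_set: CdsSet, code: int = 11) -> ProteinSet:
    """Translate every CDS of a :class:`CdsSet` into a :class:`ProteinSet`."""
    proteins = [translate_cds(seq, code) for seq in cds_set.sequences()]
    return ProteinSet(genome_id=cds_set.genome_id, proteins=[p for p in proteins if p])


_TAXONOMY_COLUMNS = ["genome_id", "phylum", "genus", "species", "strain"]


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated taxonomy table (genome_id, phylum, genus, species,
    strain).

    Rows with an empty phylum are excluded with a logged warning; duplicate
    genome ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy table missing columns: {missing}")
    df = df[_TAXONOMY_COLUMNS]
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise FormatError(f"duplicate genome_id in taxonomy table: {dups}")
    no_phylum = df["phylum"].str.strip() == ""
    if no_phylum.any():
        logger.warning(
            "excluding %d genomes without a phylum: %s",
            int(no_phylum.sum()), df.loc[no_phylum, "genome_id"].tolist(),
        )
        df = df[~no_phylum]
    return df.reset_index(drop=True)


def taxonomy_assignments(df: pd.DataFrame) -> list[TaxonomyAssignment]:
    return [TaxonomyAssignment(**row) for row in df.to_dict("records")]


def write_results_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a labelled table as TSV with 12 significant digits.

    Reading the written file back reproduces labels and values to the stored
    precision, so downstream stages can be re-run from the files alone.
    """
    if index and table.index.duplicated().any():
        raise ContractViolation("row labels must be unique")
    if table.columns.duplicated().any():
        raise ContractViolation("column labels must be unique")
    table.to_csv(path, sep="\t", float_format="%.12g", index=index)


def read_results_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
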