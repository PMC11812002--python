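"""Protein metadata from FASTA files and iBAQ computation.

Quantification tools differ in which protein metadata they echo, so the
pipeline re-derives it straight from the search database: sequence length,
the number of theoretically observable tryptic peptides, the gene name (the
``GN=`` tag of UniProt headers), and the description line.

iBAQ (intensity-based absolute quantitation) divides a protein's summed
peptide intensity by its number of theoretical tryptic peptides, making
abundances roughly comparable *between* proteins within a sample.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# classical observable-peptide window for iBAQ: fully tryptic, 6-30 residues,
# zero missed cleavages
MIN_PEPTIDE_LENGTH = 6
MAX_PEPTIDE_LENGTH = 30

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")
_GENE_TAG = re.compile(r"\bGN=(\S+)")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinInfo:
    protein_id: str
    description: str
    gene_name: str | None
    length: int
    n_tryptic: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id}: length must be >= 1")
        if not 0 <= self.n_tryptic <= self.length:
            raise ValueError(f"protein {self.protein_id}: implausible n_tryptic")


def digest_tryptic(sequence: str) -> list[str]:
    """In-silico tryptic digest: cleave after K or R unless followed by P.

    Zero missed cleavages; fragments concatenate back to the input sequence.
    """
    seq = sequence.upper()
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            fragments.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        fragments.append(seq[start:])
    return fragments


def count_tryptic_peptides(
    sequence: str,
    min_len: int = MIN_PEPTIDE_LENGTH,
    max_len: int = MAX_PEPTIDE_LENGTH,
) -> int:
    """Number of fully tryptic fragments within the observable length window."""
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    return sum(min_len <= len(f) <= max_len for f in digest_tryptic(sequence))


def parse_header(header: str) -> tuple[str, str, str | None]:
    """Split a FASTA header into (accession, description, gene_name).

    UniProt ``sp|ACC|NAME desc`` headers yield the accession between the
    pipes; anything else falls back to the first whitespace-delimited token.
    """
    header = header.strip().lstrip(">")
    m = _UNIPROT_HEADER.match(header)
    accession = m.group(1) if m else header.split()[0] if header.split() else header
    gm = _GENE_TAG.search(header)
    gene = gm.group(1) if gm else None
    parts = header.split(None, 1)
    description = parts[1] if len(parts) > 1 else ""
    return accession, description, gene


def parse_fasta_info(
    path: str | Path,
    min_len: int = MIN_PEPTIDE_LENGTH,
    max_len: int = MAX_PEPTIDE_LENGTH,
) -> dict[str, ProteinInfo]:
    """Extract per-protein metadata from a (possibly gzipped) FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    infos: dict[str, ProteinInfo] = {}
    warned_nonstandard = False
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            accession, description, gene = parse_header(record.description)
            seq = str(record.seq).upper()
            if not seq:
                logger.warning("skipping empty sequence for %s", accession)
                continue
            if not warned_nonstandard and set(seq) - _STANDARD_AA:
                logger.warning(
                    "non-standard residues in %s (treated as ordinary residues)", accession
                )
                warned_nonstandard = True
            if accession in infos:
                logger.warning("duplicate accession %s; keeping first", accession)
                continue
            infos[accession] = ProteinInfo(
                protein_id=accession,
                description=description,
                gene_name=gene,
                length=len(seq),
                n_tryptic=count_tryptic_peptides(seq, min_len, max_len),
            )
    if not infos:
        raise ValueError(f"no sequences found in FASTA file {path}")
    return infos


def compute_ibaq(total_intensity: float, info: ProteinInfo | None) -> float:
    """iBAQ = summed peptide intensity / number of theoretical tryptic peptides.

    A zero theoretical-peptide count is clamped to 1 (the value is then only a
    total intensity and is flagged in the report tables).  A missing intensity
    stays missing.
    """
    if total_intensity is None or (isinstance(total_intensity, float) and np.isnan(total_intensity)):
        return np.nan
    divisor = max(info.n_tryptic, 1) if info is not None else 1
    return float(total_intensity) / divisor


def protein_info_frame(infos: dict[str, ProteinInfo], proteins: list[str]) -> pd.DataFrame:
    """Tabulate ProteinInfo for the proteins seen in the data.

    Proteins absent from the FASTA get a row with missing fields (and are
    collected into a warning), never an error: the database and the search
    output routinely drift apart.
    """
    rows = []
    missing = []
    for p in proteins:
        info = infos.get(p)
        if info is None:
            missing.append(p)
            rows.append(
                {"protein_id": p, "description": None, "gene_name": None,
                 "length": np.nan, "n_tryptic": np.nan}
            )
        else:
            rows.append(
                {"protein_id": p, "description": info.description,
                 "gene_name": info.gene_name, "length": info.length,
                 "n_tryptic": info.n_tryptic}
            )
    if missing:
        logger.warning("%d proteins in data but not in FASTA (e.g. %s)",
                       len(missing), missing[:5])
    return pd.DataFrame(rows)


def ibaq_table(
    table,
    infos: dict[str, ProteinInfo],
    annotation=None,
) -> pd.DataFrame:
    """Per-sample iBAQ values (proteins x samples), linear scale.

    ``table`` is the peptide-level tidy table on *linear* intensities; per
    (protein, sample) the peptide intensities are summed and divided by the
    theoretical peptide count.  If an annotation is given, per-group means are
    appended as ``ibaq_mean_<group>`` columns.
    """
    r = table.roles
    totals = table.data.groupby([r.protein_id, r.sample_id], observed=True)[r.intensity].sum()
    wide = totals.unstack(r.sample_id)
    divisors = pd.Series(
        {p: max(infos[p].n_tryptic, 1) if p in infos else 1 for p in wide.index}
    )
    ibaq = wide.div(divisors, axis=0)
    ibaq.index.name = "protein_id"
    if annotation is not None:
        group_of = annotation.group_of()
        for g in annotation.groups:
            cols = [s for s in ibaq.columns if group_of.get(s) == g]
            if cols:
                ibaq[f"ibaq_mean_{g}"] = ibaq[cols].mean(axis=1)
    return ibaq
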