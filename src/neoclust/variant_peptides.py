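"""Context-peptide construction and candidate-epitope enumeration.

A coding SNV that changes one amino acid is represented by a 21-mer
"context" peptide: ten residues of flanking protein sequence on each
side of the mutated position (truncated where the protein ends).  Every
8- to 11-mer window of that context that covers the mutated residue is a
candidate MHC class I epitope; the paired wild-type k-mer differs at
exactly one position.

Protein positions are 1-based in input records; windows are 0-based
half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: residues of flanking sequence on each side of the mutation
CONTEXT_FLANK = 10

#: inclusive candidate-epitope length range presented by MHC I
MIN_K, MAX_K = 8, 11


class ReferenceMismatchError(ValueError):
    """Protein sequence does not carry the expected reference residue."""


@dataclass(frozen=True)
class SnvRecord:
    """A single-nucleotide variant at the protein level."""

    snv_id: str
    gene: str
    protein_pos: int  # 1-based position of the substituted residue
    ref_aa: str
    alt_aa: str
    expressed: bool = True
    validated: bool = True

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"{self.snv_id}: protein_pos must be >= 1")
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise ValueError(f"{self.snv_id}: non-canonical amino acid letters")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.snv_id}: ref_aa equals alt_aa")


@dataclass(frozen=True)
class ContextPeptide:
    """Paired mutant/wild-type context around one SNV.

    ``mut_offset`` is the 0-based index of the mutated residue within the
    (possibly truncated) context; for a full-length context it is 10.
    """

    snv_id: str
    mut_seq: str
    wt_seq: str
    mut_offset: int

    def __post_init__(self) -> None:
        if len(self.mut_seq) != len(self.wt_seq):
            raise ValueError(f"{self.snv_id}: mutant/WT context length mismatch")
        diffs = [i for i, (a, b) in enumerate(zip(self.mut_seq, self.wt_seq)) if a != b]
        if diffs != [self.mut_offset]:
            raise ValueError(
                f"{self.snv_id}: contexts must differ exactly at mut_offset "
                f"{self.mut_offset}, found differences at {diffs}"
            )

    def __len__(self) -> int:
        return len(self.mut_seq)


@dataclass(frozen=True)
class CandidateEpitope:
    """One mutation-containing k-mer window of a context peptide."""

    snv_id: str
    start: int  # 0-based offset into the context
    length: int
    mut_kmer: str
    wt_kmer: str


def build_context(snv: SnvRecord, protein_seq: str) -> ContextPeptide:
    """Build the 21-mer mutant/WT context peptide for one SNV.

    The window spans ``CONTEXT_FLANK`` residues either side of the
    mutated position and is truncated (never padded) where the protein
    terminates.

    Raises
    ------
    ReferenceMismatchError
        If ``protein_seq`` does not carry ``snv.ref_aa`` at
        ``snv.protein_pos`` (1-based).
    """
    pos0 = snv.protein_pos - 1
    if pos0 >= len(protein_seq):
        raise ReferenceMismatchError(
            f"{snv.snv_id}: protein_pos {snv.protein_pos} beyond protein "
            f"of length {len(protein_seq)}"
        )
    if protein_seq[pos0] != snv.ref_aa:
        raise ReferenceMismatchError(
            f"{snv.snv_id}: expected {snv.ref_aa} at protein position "
            f"{snv.protein_pos}, found {protein_seq[pos0]}"
        )
    lo = max(0, pos0 - CONTEXT_FLANK)
    hi = min(len(protein_seq), pos0 + CONTEXT_FLANK + 1)
    wt = protein_seq[lo:hi]
    off = pos0 - lo
    mut = wt[:off] + snv.alt_aa + wt[off + 1 :]
    return ContextPeptide(snv_id=snv.snv_id, mut_seq=mut, wt_seq=wt, mut_offset=off)


def enumerate_candidates(
    ctx: ContextPeptide, k_range: Iterable[int] = range(MIN_K, MAX_K + 1)
) -> list[CandidateEpitope]:
    """Enumerate all k-mer windows of ``ctx`` that cover the mutation.

    Windows are returned sorted by (length, start); duplicates arising
    from repetitive sequence are retained since provenance (start
    offset) matters downstream.  A context shorter than the smallest k
    yields an empty list with a logged warning.
    """
    ks = sorted(set(k_range))
    if any(k < MIN_K or k > MAX_K for k in ks):
        raise ValueError(f"k_range must lie within [{MIN_K}, {MAX_K}], got {ks}")
    n = len(ctx)
    if n < min(ks, default=MIN_K):
        logger.warning(
            "context %s of length %d shorter than minimum k=%d; no candidates",
            ctx.snv_id,
            n,
            min(ks, default=MIN_K),
        )
        return []
    out: list[CandidateEpitope] = []
    for k in ks:
        if k > n:
            continue
        first = max(0, ctx.mut_offset - k + 1)
        last = min(n - k, ctx.mut_offset)
        for start in range(first, last + 1):
            out.append(
                CandidateEpitope(
                    snv_id=ctx.snv_id,
                    start=start,
                    length=k,
                    mut_kmer=ctx.mut_seq[start : start + k],
                    wt_kmer=ctx.wt_seq[start : start + k],
                )
            )
    return out


def enumerate_all(
    snvs: Sequence[SnvRecord],
    proteins: dict[str, str],
    k_range: Iterable[int] = range(MIN_K, MAX_K + 1),
) -> tuple[list[ContextPeptide], list[CandidateEpitope]]:
    """Build contexts and candidates for a batch of SNVs.

    ``proteins`` maps gene name to protein sequence.  SNVs whose gene is
    missing or whose reference residue mismatches are skipped with a
    logged diagnostic rather than aborting the batch.
    """
    contexts: list[ContextPeptide] = []
    candidates: list[CandidateEpitope] = []
    for snv in snvs:
        seq = proteins.get(snv.gene)
        if seq is None:
            logger.warning("%s: no protein sequence for gene %s", snv.snv_id, snv.gene)
            continue
        try:
            ctx = build_context(snv, seq)
        except ReferenceMismatchError as exc:
            logger.warning("skipping SNV: %s", exc)
            continue
        contexts.append(ctx)
        candidates.extend(enumerate_candidates(ctx, k_range))
    return contexts, candidates
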