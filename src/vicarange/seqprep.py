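"""Alignment I/O, haplotype collapsing, and the coding-frame quality check.

Pre-phylogenetic data handling for a protein-coding mitochondrial marker:
identical sequences are collapsed to haplotypes before tree building, and
every sequence is screened for internal stop codons under the vertebrate
mitochondrial code (a frameshift or misalignment detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "HaplotypeSet",
    "check_coding",
    "CodingViolation",
]

MISSING = {"-", "?", "N", "n"}


def read_fasta(path: str) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    _check_aligned(records)
    return records


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n{seq}\n")


def _check_aligned(records: list[tuple[str, str]]) -> None:
    if not records:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    labels = [l for l, _ in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")


@dataclass
class HaplotypeSet:
    """Unique haplotypes with the collapse mapping back to input labels."""

    haplotypes: list[str]  # representative sequences, input order of first member
    members: list[list[str]]  # parallel: labels collapsed into each haplotype
    representative: list[str] = field(default_factory=list)  # label of each rep

    @property
    def counts(self) -> list[int]:
        return [len(m) for m in self.members]

    def __len__(self) -> int:
        return len(self.haplotypes)

    def mapping(self) -> dict[str, int]:
        return {lbl: i for i, mem in enumerate(self.members) for lbl in mem}

    def write_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype\tcount\tmembers\n")
            for i, mem in enumerate(self.members):
                fh.write(f"H{i + 1}\t{len(mem)}\t{','.join(mem)}\n")


def collapse_haplotypes(
    records: list[tuple[str, str]], ignore_missing: bool = False
) -> HaplotypeSet:
    """Group aligned sequences into haplotypes.

    By default two records share a haplotype iff their sequences are
    identical site-by-site.  With ``ignore_missing``, sites where either
    record has '-', '?' or 'N' are skipped in the comparison, and grouping is
    the transitive closure of that (non-transitive) pairwise relation.
    """
    _check_aligned(records)
    if not ignore_missing:
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        for label, seq in records:
            if seq not in groups:
                groups[seq] = []
                order.append(seq)
            groups[seq].append(label)
        return HaplotypeSet(
            haplotypes=order,
            members=[groups[s] for s in order],
            representative=[groups[s][0] for s in order],
        )

    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _match_ignore_missing(records[i][1], records[j][1]):
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idxs: idxs[0])
    return HaplotypeSet(
        haplotypes=[records[idxs[0]][1] for idxs in ordered],
        members=[[records[i][0] for i in idxs] for idxs in ordered],
        representative=[records[idxs[0]][0] for idxs in ordered],
    )


def _match_ignore_missing(a: str, b: str) -> bool:
    return all(x == y or x in MISSING or y in MISSING for x, y in zip(a, b))


@dataclass
class CodingViolation:
    label: str
    codon_index: int  # 0-based codon number within the frame
    position: int  # 0-based site of the codon's first base
    codon: str
    kind: str  # "stop" or "untranslatable"


def check_coding(
    records: list[tuple[str, str]],
    code: int = 2,
    frame: int = 0,
) -> list[CodingViolation]:
    """Report internal stop codons and untranslatable codons per record.

    ``code`` is an NCBI genetic-code id (2 = vertebrate mitochondrial,
    the default for cytochrome b).  A terminal stop codon is not a
    violation; codons containing gaps or ambiguity codes are reported as
    untranslatable rather than translated.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    violations: list[CodingViolation] = []
    for label, seq in records:
        coding = seq[frame:]
        n_codons = len(coding) // 3
        for ci in range(n_codons):
            codon = coding[3 * ci : 3 * ci + 3]
            if codon in stops:
                if ci == n_codons - 1:
                    continue  # terminal stop is fine
                violations.append(
                    CodingViolation(label, ci, frame + 3 * ci, codon, "stop")
                )
            elif any(b not in "ACGT" for b in codon):
                violations.append(
                    CodingViolation(label, ci, frame + 3 * ci, codon, "untranslatable")
                )
    return violations
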