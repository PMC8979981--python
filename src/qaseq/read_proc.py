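"""FASTQ streaming, primer-based module assignment and UMI extraction.

Each read is laid out as ``[UMI][fwd_primer][insert]``.  Assignment is
alignment-free: the bases after the UMI are compared against every
module's forward primer by Hamming distance and the read is assigned to
the unique module within ``max_mismatches``; ties and no-hits are left
unassigned.  This substitutes genome alignment — amplicon identity is
fully determined by the primer sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from qaseq.errors import DomainError
from qaseq.io import open_text, metadata_header
from qaseq.panel import Panel

UNASSIGNED = "*"


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    module_id: str | None
    umi: str
    insert_seq: str
    n_primer_mismatches: int
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.module_id is not None


class _PrimerIndex:
    """Exact-match fast path plus Hamming-distance fallback."""

    def __init__(self, panel: Panel):
        self.umi_length = panel.umi_length
        self.entries = [(m.module_id, m.fwd_primer) for m in panel.modules]
        self.min_primer_len = min(len(p) for _, p in self.entries)
        exact: dict[str, str | None] = {}
        for module_id, primer in self.entries:
            # a primer shared by two modules can never be assigned uniquely
            exact[primer] = None if primer in exact else module_id
        self.exact = exact

    def lookup(self, seq: str, max_mismatches: int) -> tuple[str | None, int, str]:
        u = self.umi_length
        if len(seq) < u + self.min_primer_len:
            return None, -1, "too_short"
        best_id: str | None = None
        best_dist = max_mismatches + 1
        tie = False
        for module_id, primer in self.entries:
            window = seq[u : u + len(primer)]
            if len(window) < len(primer):
                continue
            if window == primer:
                dist = 0
            else:
                dist = 0
                limit = min(best_dist, max_mismatches)
                for a, b in zip(window, primer):
                    if a != b:
                        dist += 1
                        if dist > limit:
                            break
            if dist < best_dist:
                best_id, best_dist, tie = module_id, dist, False
            elif dist == best_dist and dist <= max_mismatches:
                tie = True
        if best_dist > max_mismatches:
            return None, -1, "no_match"
        if tie:
            return None, best_dist, "ambiguous"
        return best_id, best_dist, ""


def assign_read(
    seq: str, panel: Panel, max_mismatches: int = 2, read_id: str = "", _index: _PrimerIndex | None = None
) -> AssignedRead:
    """Assign a single read to a panel module and extract its UMI."""
    index = _index if _index is not None else _PrimerIndex(panel)
    u = panel.umi_length
    # exact fast path
    module_id = None
    dist = -1
    reason = ""
    if len(seq) >= u + index.min_primer_len:
        hit = index.exact.get(seq[u : u + index.min_primer_len])
        # exact dict only valid when all primers share the minimum length
        hit = hit if hit is not None and len(panel.module(hit).fwd_primer) == index.min_primer_len else None
        if hit is not None:
            module_id, dist = hit, 0
        else:
            module_id, dist, reason = index.lookup(seq, max_mismatches)
    else:
        reason = "too_short"
    if module_id is None:
        return AssignedRead(read_id, None, "", "", dist, reason)
    primer_len = len(panel.module(module_id).fwd_primer)
    return AssignedRead(
        read_id=read_id,
        module_id=module_id,
        umi=seq[:u],
        insert_seq=seq[u + primer_len :],
        n_primer_mismatches=dist,
    )


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) records from a FASTQ(.gz) file."""
    with open_text(path, "rt") as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper()


def assign_fastq(
    path: str | Path, panel: Panel, max_mismatches: int = 2
) -> Iterator[AssignedRead]:
    """Stream a FASTQ file through primer assignment."""
    index = _PrimerIndex(panel)
    # exact dict is only a valid shortcut when all primers share one length
    uniform = len({len(p) for _, p in index.entries}) == 1
    u = panel.umi_length
    primer_len_by_id = {m.module_id: len(m.fwd_primer) for m in panel.modules}
    for read_id, seq in iter_fastq(path):
        module_id: str | None = None
        dist = -1
        reason = ""
        if uniform and len(seq) >= u + index.min_primer_len:
            module_id = index.exact.get(seq[u : u + index.min_primer_len])
            dist = 0
        if module_id is None:
            module_id, dist, reason = index.lookup(seq, max_mismatches)
        if module_id is None:
            yield AssignedRead(read_id, None, "", "", dist, reason)
        else:
            plen = primer_len_by_id[module_id]
            yield AssignedRead(read_id, module_id, seq[:u], seq[u + plen :], dist)


def on_target_rate(assignments: Iterable[AssignedRead]) -> float:
    """Fraction of reads assigned to a panel module."""
    total = 0
    hit = 0
    for rec in assignments:
        total += 1
        hit += rec.assigned
    if total == 0:
        raise DomainError("on_target_rate requires a nonempty read set")
    return hit / total


def write_assignments(
    assignments: Iterable[AssignedRead], path: str | Path, params: dict | None = None
) -> tuple[int, int]:
    """Write an assignment TSV; returns (n_total, n_assigned)."""
    total = assigned = 0
    with open_text(path, "wt") as handle:
        handle.write(metadata_header("assign", params) + "\n")
        handle.write("read_id\tmodule_id\tumi\tinsert_seq\tmismatches\n")
        for rec in assignments:
            total += 1
            if rec.assigned:
                assigned += 1
                handle.write(
                    f"{rec.read_id}\t{rec.module_id}\t{rec.umi}\t"
                    f"{rec.insert_seq}\t{rec.n_primer_mismatches}\n"
                )
            else:
                handle.write(f"{rec.read_id}\t{UNASSIGNED}\t.\t.\t{rec.n_primer_mismatches}\n")
    return total, assigned


def read_assignments(path: str | Path) -> Iterator[AssignedRead]:
    """Stream an assignment TSV back as AssignedRead records."""
    with open_text(path, "rt") as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("read_id\t"):
                continue
            read_id, module_id, umi, insert, mism = line.rstrip("\n").split("\t")
            if module_id == UNASSIGNED:
                yield AssignedRead(read_id, None, "", "", int(mism))
            else:
                yield AssignedRead(read_id, module_id, umi, insert, int(mism))
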