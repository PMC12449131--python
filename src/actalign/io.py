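"""FASTA input, result output and logging helpers.

Results are emitted as a documented TSV (one row per pair, header first,
columns: query_id, target_id, score, q_start, q_end, t_start, t_end, cigar,
status) or as a pretty format showing the gapped pair with a ``|`` match
line.  Coordinates are 1-based inclusive; an empty (score-0) alignment
renders its coordinates as 0 and its CIGAR as ``*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO

from actalign.actors import JobReport, TaskResult
from actalign.core import DNA_ALPHABET, Sequence

logger = logging.getLogger(__name__)

TSV_COLUMNS = (
    "query_id",
    "target_id",
    "score",
    "q_start",
    "q_end",
    "t_start",
    "t_end",
    "cigar",
    "status",
)


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class OutputRecord:
    query_id: str
    target_id: str
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    cigar: str
    status: str

    def row(self) -> str:
        return "\t".join(
            str(v)
            for v in (
                self.query_id,
                self.target_id,
                self.score,
                self.q_start,
                self.q_end,
                self.t_start,
                self.t_end,
                self.cigar or "*",
                self.status,
            )
        )


def read_fasta(path, alphabet: str = DNA_ALPHABET) -> List[Sequence]:
    """Read a multi-line FASTA file into validated sequences.

    The id is the header text up to the first whitespace; residues are
    case-folded to upper.  Duplicate ids are rejected, blank lines are
    ignored, and an empty file yields an empty list with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                break
        else:
            logger.warning("%s: empty FASTA file", path)
            return []
    seqs: List[Sequence] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {record.id!r}")
        seen.add(record.id)
        seqs.append(Sequence(record.id, str(record.seq), alphabet))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for k in range(0, len(s.residues), width):
                fh.write(s.residues[k : k + width] + "\n")


def record_from_task(tr: TaskResult) -> OutputRecord:
    r = tr.result
    if tr.status != "ok" or r is None:
        return OutputRecord(tr.query_id, tr.target_id, 0, 0, 0, 0, 0, "*", "failed")
    return OutputRecord(
        query_id=tr.query_id,
        target_id=tr.target_id,
        score=r.score,
        q_start=r.query_start,
        q_end=r.query_end,
        t_start=r.target_start,
        t_end=r.target_end,
        cigar=r.cigar or "*",
        status="ok",
    )


def records_from_report(report: JobReport) -> List[OutputRecord]:
    return [record_from_task(tr) for tr in report.results]


def render_tsv(records: Iterable[OutputRecord]) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    lines.extend(r.row() for r in records)
    return "\n".join(lines) + "\n"


def _match_line(a: str, b: str) -> str:
    return "".join("|" if x == y and x != "-" else " " for x, y in zip(a, b))


def render_pretty(report: JobReport, width: int = 60) -> str:
    """Gapped alignment pairs with a match line between them."""
    chunks: List[str] = []
    for tr in report.results:
        r = tr.result
        head = f"# {tr.query_id} vs {tr.target_id}"
        if tr.status != "ok" or r is None:
            chunks.append(f"{head}\n  FAILED: {tr.error}\n")
            continue
        if r.is_empty:
            chunks.append(f"{head}\n  score 0 (no alignment)\n")
            continue
        if r.is_score_only:
            chunks.append(
                f"{head}\n  score {r.score} ending at query {r.query_end}, "
                f"target {r.target_end} (score-only)\n"
            )
            continue
        lines = [
            f"{head}",
            f"  score {r.score}  query {r.query_start}-{r.query_end}  "
            f"target {r.target_start}-{r.target_end}  cigar {r.cigar}",
        ]
        for k in range(0, len(r.aligned_query), width):
            aq = r.aligned_query[k : k + width]
            at = r.aligned_target[k : k + width]
            lines.append(f"  q: {aq}")
            lines.append(f"     {_match_line(aq, at)}")
            lines.append(f"  t: {at}")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


def write_results(
    records: List[OutputRecord],
    path,
    fmt: str = "tsv",
    report: Optional[JobReport] = None,
) -> None:
    """Write job output; ``fmt`` is ``tsv`` or ``pretty`` (the latter needs
    the full report for the gapped strings)."""
    if fmt not in ("tsv", "pretty"):
        raise ValueError(f"unknown output format {fmt!r}")
    if fmt == "pretty" and report is None:
        raise ValueError("pretty format requires the JobReport")
    text = render_tsv(records) if fmt == "tsv" else render_pretty(report)
    with open(path, "w") as fh:
        fh.write(text)
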