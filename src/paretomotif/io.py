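"""File formats and reports: FASTA, 6-column BED, MEME minimal motifs.

FASTA parsing goes through Biopython; BED and the MEME minimal motif
format are simple enough to write directly.  Coordinates in BED are
0-based half-open; human-readable reports print 1-based inclusive
positions.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Candidate,
    FitnessVector,
    ProfileMatrix,
    SequenceSet,
    SiteAnnotation,
    ValidationError,
    consensus_string,
    profile_counts,
    similarity_score,
    site_matrix,
)


def read_fasta(path: str | Path, *, strict: bool = True) -> SequenceSet:
    """Read a multi-record FASTA file into a validated SequenceSet."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return SequenceSet(records, strict=strict)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(recs)


def write_bed(sites: list[SiteAnnotation], path: str | Path) -> None:
    """Write sites as 6-column BED (score = similarity x 1000, rounded)."""
    with open(path, "w") as fh:
        for s in sites:
            score = int(round(s.score * 1000))
            fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{s.name}\t{score}\t{s.strand}\n")


def read_bed(path: str | Path) -> list[SiteAnnotation]:
    sites = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{ln}: fewer than 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "site"
        score = float(fields[4]) / 1000 if len(fields) > 4 else 0.0
        strand = fields[5] if len(fields) > 5 else "+"
        sites.append(SiteAnnotation(chrom, start, end, name, score, strand))
    return sites


@dataclass(frozen=True)
class MotifReport:
    """Everything reported for one Pareto-front member."""

    candidate: Candidate
    fitness: FitnessVector
    consensus: str
    sites: tuple[str, ...]
    counts: np.ndarray  # 4 x width

    @classmethod
    def from_candidate(cls, candidate: Candidate, seqs: SequenceSet,
                       width_max: int = 20) -> "MotifReport":
        mat = site_matrix(candidate.width, np.asarray(candidate.starts), seqs)
        counts = profile_counts(mat)
        profile = ProfileMatrix(counts)
        fv = FitnessVector(similarity_score(profile), candidate.width / width_max)
        sites = tuple(seqs.sequences[i][p:p + candidate.width]
                      for i, p in enumerate(candidate.starts))
        return cls(candidate, fv, consensus_string(profile), sites, counts)


def front_reports(front, seqs: SequenceSet, width_max: int = 20) -> list[MotifReport]:
    return [MotifReport.from_candidate(cand, seqs, width_max)
            for cand, _, _ in front]


def format_report(reports: list[MotifReport], seqs: SequenceSet) -> str:
    """Human-readable motif report (1-based inclusive coordinates)."""
    buf = _stdio.StringIO()
    buf.write(f"Pareto front: {len(reports)} motif(s) from {seqs.N} sequences\n")
    for rep in reports:
        c = rep.candidate
        buf.write(
            f"\nmotif width={c.width} consensus={rep.consensus} "
            f"similarity={rep.fitness.similarity:.3f} "
            f"norm_length={rep.fitness.norm_length:.3f}\n"
        )
        for i, (ident, _) in enumerate(seqs):
            p = c.starts[i]
            buf.write(f"  {ident}\t{p + 1}-{p + c.width}\t{rep.sites[i]}\n")
    return buf.getvalue()


def report_table(reports: list[MotifReport]) -> str:
    """TSV summary, one row per front member."""
    lines = ["width\tconsensus\tsimilarity\tnorm_length"]
    for rep in reports:
        lines.append(
            f"{rep.candidate.width}\t{rep.consensus}\t"
            f"{rep.fitness.similarity:.3f}\t{rep.fitness.norm_length:.3f}"
        )
    return "\n".join(lines) + "\n"


def write_meme_motifs(reports: list[MotifReport], path: str | Path,
                      background: np.ndarray | None = None) -> None:
    """Write the front's count matrices in MEME minimal motif format."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for rep in reports:
            n = int(rep.counts[:, 0].sum())
            w = rep.counts.shape[1]
            fh.write(f"MOTIF {rep.consensus}\n")
            fh.write(
                f"letter-probability matrix: alphabet= 4 w= {w} nsites= {n} E= 0\n"
            )
            freqs = rep.counts / rep.counts.sum(axis=0, keepdims=True)
            for j in range(w):
                row = np.round(freqs[:, j], 6)
                row[np.argmax(row)] += round(1.0 - row.sum(), 6)
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_outputs(front, seqs: SequenceSet, prefix: str | Path,
                  width_max: int = 20) -> dict[str, Path]:
    """Write BED sites, text + TSV reports and MEME motifs for a front.

    Returns the paths written, keyed by kind.
    """
    if not front:
        raise ValidationError("cannot write outputs for an empty front")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    reports = front_reports(front, seqs, width_max)
    sites: list[SiteAnnotation] = []
    for rep in reports:
        c = rep.candidate
        label = f"w{c.width}_{rep.consensus}"
        for i, p in enumerate(c.starts):
            sites.append(SiteAnnotation(seqs.ids[i], p, p + c.width, label,
                                        rep.fitness.similarity))
    paths = {
        "bed": prefix.with_suffix(".sites.bed"),
        "report": prefix.with_suffix(".report.txt"),
        "tsv": prefix.with_suffix(".motifs.tsv"),
        "meme": prefix.with_suffix(".meme.txt"),
    }
    write_bed(sites, paths["bed"])
    paths["report"].write_text(format_report(reports, seqs))
    paths["tsv"].write_text(report_table(reports))
    write_meme_motifs(reports, paths["meme"])
    return paths
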