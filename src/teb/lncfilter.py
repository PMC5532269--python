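"""Three-step novel-lncRNA filter for assembled transcripts.

Applied to transcripts assembled against a reference annotation and labelled
with Cuffcompare-style class codes:

1. keep class codes {j, i, o, u, x} (novel isoform / intronic / exonic
   overlap / intergenic / antisense) and drop single-exon transcripts;
2. drop transcripts shorter than 200 nt or with a longest ORF above 300 nt
   (ORF length counted in nucleotides including the stop codon, sense
   strand only);
3. drop transcripts with a coding-potential score above 0 (CPC sign
   convention; scores are consumed as input, transcripts without a score
   pass through with a warning).

Every step records telescoping input/output counts and each transcript's
first failing rule in a :class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

DEFAULT_CLASS_CODES = frozenset("jioux")
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class AssembledTranscript:
    transcript_id: str
    class_code: str
    n_exons: int
    sequence: str
    coding_potential: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.n_exons < 1:
            raise ValueError(f"{self.transcript_id}: exon count must be >= 1")

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def orf_nt(self) -> int:
        return longest_orf(self.sequence)


@dataclass
class FilterReport:
    steps: list = field(default_factory=list)  # (name, n_in, n_out)
    fates: dict = field(default_factory=dict)  # transcript_id -> first failing rule
    warnings: list = field(default_factory=list)

    def record(self, name: str, before: list, after: list) -> None:
        kept = {t.transcript_id for t in after}
        for t in before:
            if t.transcript_id not in kept:
                self.fates.setdefault(t.transcript_id, name)
        self.steps.append((name, len(before), len(after)))

    def telescopes(self) -> bool:
        return all(
            self.steps[i][2] == self.steps[i + 1][1] for i in range(len(self.steps) - 1)
        )


# ------------------------------------------------------------------- steps
def select_novel_classes(
    transcripts: list[AssembledTranscript],
    allowed=DEFAULT_CLASS_CODES,
    report: FilterReport | None = None,
) -> list[AssembledTranscript]:
    known = set("=cjeiopruxs.")
    for t in transcripts:
        if t.class_code not in known and report is not None:
            report.warnings.append(f"unknown class code {t.class_code!r} for {t.transcript_id}")
    out = [t for t in transcripts if t.class_code in allowed]
    if report is not None:
        report.record("class_code", transcripts, out)
    return out


def remove_single_exon(
    transcripts: list[AssembledTranscript], report: FilterReport | None = None
) -> list[AssembledTranscript]:
    out = [t for t in transcripts if t.n_exons >= 2]
    if report is not None:
        report.record("single_exon", transcripts, out)
    return out


def longest_orf(sequence: str) -> int:
    """Length (nt, including the stop codon) of the longest sense-strand ORF.

    An ORF is an ATG followed in-frame by the first TAA/TAG/TGA; the three
    sense frames are scanned.  A codon containing N cannot serve as a start
    or stop.  An empty sequence or one with no ORF returns 0.
    """
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def apply_lncrna_thresholds(
    transcripts: list[AssembledTranscript],
    min_len: int = 200,
    max_orf: int = 300,
    report: FilterReport | None = None,
) -> list[AssembledTranscript]:
    """Remove transcripts shorter than ``min_len`` nt or with ORF > ``max_orf`` nt."""
    out = [t for t in transcripts if t.length_nt >= min_len and t.orf_nt <= max_orf]
    if report is not None:
        report.record("length_orf", transcripts, out)
    return out


def coding_potential_screen(
    transcripts: list[AssembledTranscript],
    scores: dict | None = None,
    report: FilterReport | None = None,
) -> list[AssembledTranscript]:
    """Remove transcripts with a coding-potential score strictly above 0.

    Scores may come pre-attached to the transcripts or via ``scores``.
    Transcripts without any score pass through with a warning; score-table
    ids with no matching transcript are warned about and ignored.
    """
    scores = scores or {}
    ids = {t.transcript_id for t in transcripts}
    if report is not None:
        for unknown in sorted(set(scores) - ids):
            report.warnings.append(f"coding-potential score for unknown transcript {unknown}")
    out = []
    for t in transcripts:
        score = scores.get(t.transcript_id, t.coding_potential)
        if score is None:
            if report is not None:
                report.warnings.append(f"no coding-potential score for {t.transcript_id}")
            out.append(t)
        elif score <= 0:
            out.append(t)
    if report is not None:
        report.record("coding_potential", transcripts, out)
    return out


def filter_lncrnas(
    transcripts: list[AssembledTranscript],
    allowed=DEFAULT_CLASS_CODES,
    min_len: int = 200,
    max_orf: int = 300,
    scores: dict | None = None,
) -> tuple[list[AssembledTranscript], FilterReport]:
    """The full three-step filter in the published order."""
    report = FilterReport()
    kept = select_novel_classes(transcripts, allowed, report)
    kept = remove_single_exon(kept, report)
    kept = apply_lncrna_thresholds(kept, min_len, max_orf, report)
    kept = coding_potential_screen(kept, scores, report)
    return kept, report


# ---------------------------------------------------------------------- io
def read_transcripts(
    fasta_path, classes_path, exon_counts: dict | None = None, scores_path=None
) -> list[AssembledTranscript]:
    """Assemble transcript records from FASTA + class-code TSV (+ scores TSV).

    The class-code table is two or three tab-separated columns:
    transcript_id, class_code[, n_exons].  ``exon_counts`` overrides the
    third column when supplied (e.g. counted from an exon GTF).
    """
    codes: dict = {}
    exons: dict = dict(exon_counts or {})
    with open(classes_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith("#"):
                continue
            codes[parts[0]] = parts[1]
            if len(parts) > 2 and parts[0] not in exons:
                exons[parts[0]] = int(parts[2])
    scores: dict = {}
    if scores_path is not None:
        with open(scores_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and not parts[0].startswith("#"):
                    scores[parts[0]] = float(parts[1])
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid = rec.id
        if tid not in codes:
            continue
        out.append(
            AssembledTranscript(
                tid,
                codes[tid],
                exons.get(tid, 1),
                str(rec.seq),
                scores.get(tid),
            )
        )
    return out


def count_exons_gtf(gtf_path) -> dict:
    """Exon counts per transcript from an exon-feature GTF."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    counts: dict = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        counts[tid] = counts.get(tid, 0) + 1
    return counts
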