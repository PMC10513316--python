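"""File-format plumbing: FASTA/TSV oligo panels, qPCR and call CSVs,
candidate and tally TSVs, FASTQ reading/writing (gzip transparent).

CSV dialect is UTF-8 comma-separated with a header row; FASTQ is the
4-line standard.  Every writer here has a matching reader that parses
its output back identically.
"""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO

from blockamp.assets import parse_printed_sequence
from blockamp.concordance import SampleRecord
from blockamp.design import AssayCandidate
from blockamp.nanopore_count import BarcodeTally, TallyResult
from blockamp.qpcr_calls import DiscriminationCall, QpcrRecord
from blockamp.thermo import Oligo, ROLES

PathLike = Union[str, Path]


def open_text(path: PathLike, mode: str = "rt"):
    """Open a text file, transparently handling a .gz suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# oligo panels

def _infer_role(name: str, bases: str) -> str:
    lname = name.lower()
    if "blocker" in lname or lname.startswith("b"):
        return "blocker"
    if len(bases) >= 50:
        return "barcoded_primer"
    return "opposite_primer"


def read_oligos_tsv(path: PathLike) -> List[Oligo]:
    """Read an oligo table with columns Name, Size, Sequence and an
    optional Role column.

    Sequences may carry published-style decoration ("&" padding, "-P" /
    "P-" phosphate markers, "-" part separators), which is stripped.
    """
    oligos: List[Oligo] = []
    with open_text(path) as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                bases, three_p, five_p, _ = parse_printed_sequence(row["Sequence"])
                role = (row.get("Role") or "").strip() or _infer_role(
                    row["Name"], bases
                )
                oligos.append(
                    Oligo(
                        name=row["Name"],
                        bases=bases,
                        role=role,
                        three_prime_phosphate=three_p or role == "blocker",
                        five_prime_phosphate=five_p,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return oligos


def read_oligos_fasta(path: PathLike) -> List[Oligo]:
    """Read oligos from FASTA; the description may carry key=value
    tokens ``role=``, ``phos3=``, ``phos5=``.
    """
    oligos: List[Oligo] = []
    with open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            tokens = dict(
                t.split("=", 1) for t in rec.description.split() if "=" in t
            )
            role = tokens.get("role", "opposite_primer")
            if role not in ROLES:
                raise ValueError(f"{path}: unknown role {role!r} for {rec.id}")
            oligos.append(
                Oligo(
                    name=rec.id,
                    bases=str(rec.seq),
                    role=role,
                    three_prime_phosphate=tokens.get("phos3", "0") in ("1", "true"),
                    five_prime_phosphate=tokens.get("phos5", "0") in ("1", "true"),
                )
            )
    return oligos


def write_oligos_fasta(path: PathLike, oligos: Sequence[Oligo]) -> None:
    with open_text(path, "wt") as fh:
        for o in oligos:
            fh.write(
                f">{o.name} role={o.role} "
                f"phos3={int(o.three_prime_phosphate)} "
                f"phos5={int(o.five_prime_phosphate)}\n{o.bases}\n"
            )


# ---------------------------------------------------------------------------
# design candidates

CANDIDATE_COLUMNS = [
    "rank", "orientation", "allele_primer", "allele_seq", "tm_allele",
    "blocker", "blocker_seq", "tm_blocker", "opposite_primer",
    "opposite_seq", "tm_opposite", "score",
]


def write_candidates_tsv(
    path: PathLike, candidates: Sequence[AssayCandidate]
) -> None:
    """Write ranked candidates as TSV (best first)."""
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for rank, c in enumerate(candidates, start=1):
            writer.writerow(
                [
                    rank, c.orientation,
                    c.allele_primer.name, c.allele_primer.bases,
                    f"{c.tm_allele:.1f}",
                    c.blocker.name, c.blocker.bases, f"{c.tm_blocker:.1f}",
                    c.opposite_primer.name, c.opposite_primer.bases,
                    f"{c.tm_opposite:.1f}",
                    f"{c.score:.3f}",
                ]
            )


# ---------------------------------------------------------------------------
# qPCR records and calls

def read_qpcr_csv(path: PathLike) -> List[QpcrRecord]:
    """Read qPCR wells: sample_id, template_class, ct (empty = no
    amplification), melt_peak, max_cycles."""
    records: List[QpcrRecord] = []
    with open_text(path) as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                records.append(
                    QpcrRecord(
                        sample_id=row["sample_id"],
                        template_class=(row.get("template_class") or "unknown"),
                        ct=float(row["ct"]) if row.get("ct") else None,
                        melt_peak_celsius=(
                            float(row["melt_peak"]) if row.get("melt_peak") else None
                        ),
                        max_cycles=int(row.get("max_cycles") or 45),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_qpcr_csv(path: PathLike, records: Sequence[QpcrRecord]) -> None:
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "template_class", "ct", "melt_peak", "max_cycles"])
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.template_class,
                    "" if r.ct is None else f"{r.ct:g}",
                    "" if r.melt_peak_celsius is None else f"{r.melt_peak_celsius:g}",
                    r.max_cycles,
                ]
            )


def write_calls_csv(
    path: PathLike, calls: Sequence[Tuple[str, DiscriminationCall]]
) -> None:
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "call", "n_specific", "reason"])
        for sample_id, call in calls:
            writer.writerow(
                [sample_id, call.call, call.n_specific_replicates, call.reason]
            )


# ---------------------------------------------------------------------------
# sample call tables

def read_sample_table(path: PathLike) -> List[SampleRecord]:
    """Read a verification call table CSV; ratio "n.t." or empty means
    not sequenced (never zero)."""
    records: List[SampleRecord] = []
    with open_text(path) as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                raw = (row.get("ratio_percent") or "").strip()
                ratio = None if raw in ("", "n.t.", "nt", "NA") else float(raw)
                records.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        sanger=row["sanger"],
                        new_method=row["new_method"],
                        ratio_percent=ratio,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return records


def write_sample_table(path: PathLike, records: Sequence[SampleRecord]) -> None:
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "sanger", "new_method", "ratio_percent"])
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.sanger,
                    r.new_method,
                    "n.t." if r.ratio_percent is None else f"{r.ratio_percent:g}",
                ]
            )


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq_sequences(path: PathLike) -> Tuple[Iterable[str], int]:
    """All read sequences from a FASTQ file (plain or gzip).

    Returns (sequences, n_bad_records); malformed trailing records are
    skipped and counted rather than aborting the tally.
    """
    seqs: List[str] = []
    n_bad = 0
    with open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - (len(lines) % 4), 4):
        header, seq, plus = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith("@") or not plus.startswith("+"):
            n_bad += 1
            continue
        seqs.append(seq.upper())
    n_bad += 1 if len(lines) % 4 else 0
    return seqs, n_bad


def write_fastq(
    path: PathLike, reads: Iterable[Tuple[str, str, str]], header_comment: str = ""
) -> None:
    """Write (id, sequence, quality) triples as FASTQ.

    ``header_comment`` (e.g. the simulation seed) is appended to every
    read id after a space, keeping provenance inside the file.
    """
    suffix = f" {header_comment}" if header_comment else ""
    with open_text(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}{suffix}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# tallies

TALLY_COLUMNS = [
    "barcode_id", "n_wt", "n_mu", "n_ambiguous", "n_barcode_only",
    "ratio_percent", "sufficient_depth",
]


def write_tally_tsv(path: PathLike, result: TallyResult) -> None:
    """Per-barcode tally TSV with a trailing pool-level comment block."""
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TALLY_COLUMNS)
        for t in result.barcodes:
            writer.writerow(
                [
                    t.barcode_id, t.n_wt, t.n_mu, t.n_ambiguous, t.n_barcode_only,
                    "" if t.ratio_percent is None else f"{t.ratio_percent:.1f}",
                    int(t.sufficient_depth),
                ]
            )
        fh.write(
            f"# total_reads={result.n_total} unassigned={result.n_unassigned} "
            f"multi_barcode={result.n_multi_barcode} "
            f"bad_records={result.n_bad_records}\n"
        )


def read_tally_tsv(path: PathLike) -> TallyResult:
    barcodes: List[BarcodeTally] = []
    stats = {"total_reads": 0, "unassigned": 0, "multi_barcode": 0, "bad_records": 0}
    with open_text(path) as fh:
        rows = [ln.rstrip("\n") for ln in fh]
    header = rows[0].split("\t")
    for ln in rows[1:]:
        if ln.startswith("#"):
            for token in ln[1:].split():
                key, _, value = token.partition("=")
                if key in stats:
                    stats[key] = int(value)
            continue
        row = dict(zip(header, ln.split("\t")))
        barcodes.append(
            BarcodeTally(
                barcode_id=row["barcode_id"],
                n_wt=int(row["n_wt"]),
                n_mu=int(row["n_mu"]),
                n_ambiguous=int(row["n_ambiguous"]),
                n_barcode_only=int(row["n_barcode_only"]),
                ratio_percent=(
                    float(row["ratio_percent"]) if row["ratio_percent"] else None
                ),
                sufficient_depth=bool(int(row["sufficient_depth"])),
            )
        )
    return TallyResult(
        barcodes=barcodes,
        n_total=stats["total_reads"],
        n_unassigned=stats["unassigned"],
        n_multi_barcode=stats["multi_barcode"],
        n_bad_records=stats["bad_records"],
    )
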