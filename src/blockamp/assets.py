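"""Built-in assay definitions shipped with the package.

The oligo panel (detection primers and blockers, TA-cloning primers,
barcoded nanopore primers, standard-construction primers) and the two
verification call tables ship as plain-text package data.  Oligo
sequences are stored exactly as published: "&" characters are alignment
padding, a "-P" suffix marks a 3'-phosphate, a "P-" prefix marks a
5'-phosphate, and internal "-" separate the pad / barcode / annealing
parts of the three-part nanopore primers.  All decoration is stripped on
load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

from blockamp.concordance import SampleRecord
from blockamp.nanopore_count import BarcodeSpec
from blockamp.thermo import Oligo


@dataclass(frozen=True)
class PanelEntry:
    """One row of the shipped oligo table."""

    oligo: Oligo
    section: str  # selection | ta_cloning | nanopore | standards
    parts: tuple  # "-"-separated segments of the printed sequence


def _data_text(filename: str) -> str:
    return (
        resources.files("blockamp").joinpath("data", filename).read_text()
    )


def parse_printed_sequence(raw: str):
    """Strip Table-style decoration from a printed oligo sequence.

    Returns (bases, three_prime_phosphate, five_prime_phosphate, parts)
    where ``parts`` are the "-"-separated segments after phosphate
    markers are removed (one element for ordinary oligos, pad/barcode/
    annealing for the three-part primers).
    """
    seq = raw.strip().replace("&", "")
    five_p = seq.startswith("P-")
    if five_p:
        seq = seq[2:]
    three_p = seq.endswith("-P")
    if three_p:
        seq = seq[:-2]
    parts = tuple(p for p in seq.split("-") if p)
    return "".join(parts), three_p, five_p, parts


def load_table1(full: bool = False):
    """The published oligo panel.

    Returns ``{short_name: Oligo}`` (short name: "Primer F4" -> "F4",
    "Blocker BF1" -> "BF1"); with ``full=True`` returns
    ``{short_name: PanelEntry}`` including section and printed parts.
    """
    entries: Dict[str, PanelEntry] = {}
    text = _data_text("table1_oligos.tsv")
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        bases, three_p, five_p, parts = parse_printed_sequence(row["Sequence"])
        if len(bases) != int(row["Size"]):
            raise ValueError(
                f"{row['Name']}: parsed length {len(bases)} != "
                f"printed size {row['Size']}"
            )
        short = row["Name"].split()[-1]
        oligo = Oligo(
            name=short,
            bases=bases,
            role=row["Role"],
            three_prime_phosphate=three_p,
            five_prime_phosphate=five_p,
        )
        entries[short] = PanelEntry(oligo=oligo, section=row["Section"], parts=parts)
    if full:
        return entries
    return {name: e.oligo for name, e in entries.items()}


def default_panel() -> List[BarcodeSpec]:
    """The six shipped barcoded forward primers as a demultiplexing panel."""
    panel: List[BarcodeSpec] = []
    for name, entry in load_table1(full=True).items():
        if entry.section != "nanopore" or entry.oligo.role != "barcoded_primer":
            continue
        pad, barcode, annealing = entry.parts
        panel.append(
            BarcodeSpec(
                barcode_id=name.rsplit("_", 1)[-1],  # BRAF_Fw_BC1 -> BC1
                pad_seq=pad,
                barcode_seq=barcode,
                annealing_seq=annealing,
                five_prime_phosphate=entry.oligo.five_prime_phosphate,
            )
        )
    panel.sort(key=lambda s: s.barcode_id)
    ids = [s.barcode_seq for s in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("barcode sequences in the panel are not unique")
    return panel


def _load_sample_csv(filename: str) -> List[SampleRecord]:
    records = []
    for row in csv.DictReader(_data_text(filename).splitlines()):
        ratio_raw = (row.get("ratio_percent") or "").strip()
        ratio: Optional[float] = (
            None if ratio_raw in ("", "n.t.", "nt", "NA") else float(ratio_raw)
        )
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                sanger=row["sanger"],
                new_method=row["new_method"],
                ratio_percent=ratio,
            )
        )
    return records


def load_table2() -> List[SampleRecord]:
    """First-verification call table (22 urine-sediment samples)."""
    return _load_sample_csv("table2.csv")


def load_table3() -> List[SampleRecord]:
    """Second-verification call table (16 urine-sediment samples)."""
    return _load_sample_csv("table3.csv")
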