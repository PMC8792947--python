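"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (UTRs, miRNAs), BED3+ (single-nucleotide m6A sites with the
chrom column carrying the transcript id), bedGraph (per-nucleotide
conservation, same id convention), and two headered TSVs (expression,
CLASH chimeras). All output tables are UTF-8, tab-separated, '.' decimal.

Every reader validates against the cohort invariants (unique ids, in-range
coordinates, fragment/UTR consistency) and raises ``ValueError`` naming the
offending record, so malformed input fails at the boundary rather than
mid-analysis.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .datamodel import (
    ChimeraRecord,
    ConservationTrack,
    ExpressionRecord,
    M6ASite,
    MiRNARecord,
    TranscriptRecord,
)

EXPRESSION_HEADER = ["transcript_id", "log2fc", "basal", "perturbation"]
CHIMERA_HEADER = [
    "mirna_id", "mirna_seq", "transcript_id", "frag_start", "frag_end", "frag_seq",
]


def read_fasta(path: str | Path, species_tag: str = "") -> list[TranscriptRecord]:
    """Read 3'-UTR sequences; T->U normalized, upper-cased, ids unique."""
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            TranscriptRecord(rec.id, str(rec.seq), species_tag=species_tag)
        )
    return records


def read_mirna_fasta(path: str | Path) -> list[MiRNARecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate miRNA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(MiRNARecord(rec.id, str(rec.seq)))
    return records


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_m6a_bed(
    path: str | Path,
    transcripts: Sequence[TranscriptRecord] | None = None,
) -> list[M6ASite]:
    """Read single-nucleotide m6A sites from BED3+ (0-based half-open).

    When ``transcripts`` is given, positions are range-checked and a warning
    (not an error) is emitted for sites whose underlying base is not A —
    real modification maps contain such edge cases.
    """
    by_id = {t.transcript_id: t for t in transcripts} if transcripts else None
    sites: list[M6ASite] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        tx_id, start_s, end_s = fields[0], fields[1], fields[2]
        start, end = int(start_s), int(end_s)
        if end != start + 1:
            raise ValueError(
                f"{path}:{lineno}: m6A sites must be single-nucleotide "
                f"(got [{start},{end}))"
            )
        source = fields[3] if len(fields) > 3 else ""
        if by_id is not None:
            tx = by_id.get(tx_id)
            if tx is None:
                raise ValueError(f"{path}:{lineno}: unknown transcript {tx_id!r}")
            if not 0 <= start < len(tx):
                raise ValueError(
                    f"{path}:{lineno}: position {start} outside {tx_id} "
                    f"(length {len(tx)})"
                )
            if tx.utr3_seq[start] != "A":
                warnings.warn(
                    f"m6A site {tx_id}:{start} sits on "
                    f"{tx.utr3_seq[start]!r}, not A",
                    stacklevel=2,
                )
        sites.append(M6ASite(tx_id, start, source_tag=source))
    return sites


def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    rows = list(_data_lines(path))
    if not rows:
        return []
    first_lineno, header = rows[0]
    if header != EXPRESSION_HEADER:
        raise ValueError(
            f"{path}:{first_lineno}: expected header "
            f"{chr(9).join(EXPRESSION_HEADER)!r}"
        )
    out = []
    for lineno, fields in rows[1:]:
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        out.append(
            ExpressionRecord(fields[0], float(fields[1]), float(fields[2]), fields[3])
        )
    return out


def read_conservation_bedgraph(
    path: str | Path, transcripts: Sequence[TranscriptRecord]
) -> list[ConservationTrack]:
    """Expand bedGraph intervals into per-nucleotide tracks.

    Positions not covered by any interval stay ``NaN`` (missing), never 0.
    Returns one track per transcript that has at least one covered position.
    """
    import numpy as np

    by_id = {t.transcript_id: t for t in transcripts}
    buf: dict[str, np.ndarray] = {}
    unknown: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        tx_id, start, end, value = (
            fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
        )
        tx = by_id.get(tx_id)
        if tx is None:
            unknown.add(tx_id)
            continue
        if not (0 <= start < end <= len(tx)):
            raise ValueError(
                f"{path}:{lineno}: interval [{start},{end}) outside "
                f"{tx_id} (length {len(tx)})"
            )
        if tx_id not in buf:
            buf[tx_id] = np.full(len(tx), np.nan)
        buf[tx_id][start:end] = value
    if unknown:
        raise ValueError(
            f"{path}: conservation records for unknown transcripts: "
            f"{', '.join(sorted(unknown))}"
        )
    return [ConservationTrack(tx_id, scores) for tx_id, scores in buf.items()]


def read_chimeras_tsv(
    path: str | Path, transcripts: Sequence[TranscriptRecord]
) -> list[ChimeraRecord]:
    by_id = {t.transcript_id: t for t in transcripts}
    rows = list(_data_lines(path))
    if not rows:
        return []
    first_lineno, header = rows[0]
    if header != CHIMERA_HEADER:
        raise ValueError(
            f"{path}:{first_lineno}: expected header "
            f"{chr(9).join(CHIMERA_HEADER)!r}"
        )
    out = []
    offenders = []
    for lineno, fields in rows[1:]:
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns")
        rec = ChimeraRecord(
            fields[0], fields[1], fields[2], int(fields[3]), int(fields[4]), fields[5]
        )
        tx = by_id.get(rec.transcript_id)
        if tx is None:
            offenders.append(rec.transcript_id)
            continue
        if tx.utr3_seq[rec.frag_start:rec.frag_end] != rec.frag_seq:
            raise ValueError(
                f"{path}:{lineno}: fragment sequence does not match "
                f"{rec.transcript_id}[{rec.frag_start}:{rec.frag_end}]"
            )
        out.append(rec)
    if offenders:
        raise ValueError(
            f"{path}: chimeras on unknown transcripts: "
            f"{', '.join(sorted(set(offenders)))}"
        )
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts; used by the cohort generator and CLI)

def write_fasta(records: Sequence[TranscriptRecord] | Sequence[MiRNARecord],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            rid = getattr(rec, "transcript_id", None) or rec.mirna_id  # type: ignore[union-attr]
            seq = getattr(rec, "utr3_seq", None) or rec.seq  # type: ignore[union-attr]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_m6a_bed(sites: Sequence[M6ASite], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sites:
            name = s.source_tag or "m6A"
            fh.write(f"{s.transcript_id}\t{s.position}\t{s.position + 1}\t{name}\n")


def write_expression_tsv(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EXPRESSION_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.log2fc!r}\t{r.basal!r}\t{r.perturbation_tag}\n"
            )


def write_conservation_bedgraph(
    tracks: Sequence[ConservationTrack], path: str | Path
) -> None:
    """Emit maximal constant-value runs, skipping missing (NaN) positions."""
    import math

    with open(path, "w", encoding="utf-8") as fh:
        for tr in tracks:
            run_start = None
            run_val: float | None = None
            for i, v in enumerate([float(x) for x in tr.scores] + [math.nan]):
                if run_val is not None and v == run_val:
                    continue
                if run_val is not None:
                    fh.write(f"{tr.transcript_id}\t{run_start}\t{i}\t{run_val!r}\n")
                run_start, run_val = (
                    (i, v) if not math.isnan(v) else (None, None)
                )


def write_chimeras_tsv(records: Sequence[ChimeraRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CHIMERA_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.mirna_id}\t{r.mirna_seq}\t{r.transcript_id}\t"
                f"{r.frag_start}\t{r.frag_end}\t{r.frag_seq}\n"
            )


def write_report_tables(results: dict[str, "object"], out_dir: str | Path) -> list[Path]:
    """Write a dict of name -> pandas DataFrame as TSV files under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)  # type: ignore[attr-defined]
        paths.append(p)
    return paths
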