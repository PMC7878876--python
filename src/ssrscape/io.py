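"""Readers and writers for the formats the pipeline consumes and emits.

FASTA via Biopython (gzip transparent); SSR records as GFF3
(type ``microsatellite``) and BED6; RepeatMasker ``.out`` tables and a
GFF3 variant with a divergence attribute; narrowPeak; read-pair TSV and
SAM (via pysam); gene-model GFF3; ortholog pair TSV.  Internal
coordinates are 0-based half-open everywhere; GFF3 (1-based closed) and
RepeatMasker (1-based closed) are converted at these boundaries.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .detect import SSRRecord

logger = logging.getLogger(__name__)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read (optionally gzipped) FASTA into {seq_id: sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------- SSR records

def write_ssr_gff3(records: list[SSRRecord], path) -> None:
    """SSRs as GFF3, type ``microsatellite``, attributes Motif/Repeats/Purity."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(records):
            attrs = (f"ID=ssr{i};Motif={r.motif};Repeats={r.repeats:.2f};"
                     f"Purity={r.purity:.4f}")
            fh.write("\t".join([
                r.seq_id, "ssrscape", "microsatellite",
                str(r.start + 1), str(r.end), ".", "+", ".", attrs]) + "\n")


def read_ssr_gff3(path) -> list[SSRRecord]:
    records = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            start, end = int(f[3]) - 1, int(f[4])
            motif = attrs["Motif"]
            period = len(motif.split("/")[0])
            length = end - start
            purity = float(attrs.get("Purity", 1.0))
            records.append(SSRRecord(
                seq_id=f[0], start=start, end=end, motif=motif,
                period=period, repeats=length / period, length=length,
                mismatches=round((1 - purity) * length), purity=purity))
    return records


def write_ssr_bed(records: list[SSRRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join([
                r.seq_id, str(r.start), str(r.end),
                f"({r.motif})n", f"{r.repeats:.1f}", "+"]) + "\n")


# ----------------------------------------------------- RepeatMasker .out

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "      repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat"
    "       class/family  begin end (left)  ID\n\n")


def write_repeatmasker_out(tes, path) -> None:
    """Write TE copies (objects with seq_id/start/end/strand/family/
    te_class/divergence) as a RepeatMasker-style .out table."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, t in enumerate(tes):
            fam = f"{t.te_class}/{t.family}" if t.te_class else t.family
            fh.write(
                f"{1000:>5} {t.divergence * 100:6.1f}  0.0  0.0  "
                f"{t.seq_id:<10} {t.start + 1:>8} {t.end:>8} (0)  "
                f"{'+' if t.strand == '+' else 'C'}  {t.family:<15} "
                f"{fam:<20} 1 {t.end - t.start} (0) {i + 1}\n")


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Parse a RepeatMasker .out table.

    Returns a DataFrame with seq_id, start, end (0-based half-open),
    strand, family, te_class, divergence (fraction).  Malformed lines
    are logged and skipped.
    """
    rows, skipped = [], 0
    with _open_text(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank
            try:
                div = float(parts[1]) / 100.0
                seq_id = parts[4]
                start, end = int(parts[5]) - 1, int(parts[6])
                strand = "+" if parts[8] == "+" else "-"
                name = parts[9]
                cls_fam = parts[10]
            except (IndexError, ValueError):
                skipped += 1
                continue
            te_class = cls_fam.split("/")[0]
            family = cls_fam.split("/", 1)[1] if "/" in cls_fam else name
            rows.append((seq_id, start, end, strand, family, te_class, div))
    if skipped:
        logger.warning("read_repeatmasker_out: skipped %d malformed lines",
                       skipped)
    return pd.DataFrame(rows, columns=[
        "seq_id", "start", "end", "strand", "family", "te_class",
        "divergence"])


# ------------------------------------------------------------ narrowPeak

NARROWPEAK_COLUMNS = ["seq_id", "start", "end", "peak_id", "score", "strand",
                      "signal", "pvalue", "qvalue", "summit"]


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = NARROWPEAK_COLUMNS[:df.shape[1]]
    return df


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    cols = [c for c in NARROWPEAK_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_peak_pvalues(path) -> pd.Series:
    """Two-column peak_id -> differential p-value TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["peak_id", "diff_p"])
    return df.set_index("peak_id")["diff_p"]


# ------------------------------------------------------------ read pairs

PAIR_COLUMNS = ["pair_id", "seq_id_1", "pos_1", "seq_id_2", "pos_2",
                "sample_id"]


def read_pair_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = PAIR_COLUMNS[:df.shape[1]]
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    return df


def write_pair_tsv(pairs: pd.DataFrame, path) -> None:
    pairs[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_pairs_sam(path, min_mapq: int = 20) -> pd.DataFrame:
    """Stream mate positions from SAM/BAM (both mates mapped).

    Positions are the mapped reference starts of each mate; pairs where
    either mate has MAPQ below *min_mapq* are dropped and counted.
    """
    import pysam

    rows, dropped = [], 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.mate_is_unmapped or not aln.is_read1:
                continue
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                dropped += 1
                continue
            rows.append((aln.query_name, aln.reference_name,
                         aln.reference_start,
                         aln.next_reference_name, aln.next_reference_start,
                         "sample"))
    if dropped:
        logger.info("read_pairs_sam: dropped %d low-MAPQ pairs", dropped)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# ------------------------------------------------------------- gene GFF3

def read_gff3(path) -> pd.DataFrame:
    """Flat parse of a GFF3 into a DataFrame (0-based half-open)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((f[0], f[2], int(f[3]) - 1, int(f[4]), f[6],
                         attrs.get("ID", ""), attrs.get("Parent", ""), f[8]))
    return pd.DataFrame(rows, columns=[
        "seq_id", "type", "start", "end", "strand", "id", "parent", "attrs"])


def write_gff3(df: pd.DataFrame, path) -> None:
    """Write a gene-model table (columns as from read_gff3) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples():
            attrs = row.attrs if getattr(row, "attrs", "") else (
                (f"ID={row.id}" if row.id else "") +
                (f";Parent={row.parent}" if row.parent else ""))
            fh.write("\t".join([
                row.seq_id, "ssrscape", row.type, str(row.start + 1),
                str(row.end), ".", row.strand, ".", attrs.strip(";")]) + "\n")


# --------------------------------------------------------- ortholog TSV

def read_ortholog_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["gene_id_a", "gene_id_b"])
    return df


def write_ortholog_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False)
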