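"""Standard-format report writers (TSV, VCF breakends, BED, bedGraph).

Every writer stamps the run seed and config hash into a header comment so
outputs are traceable to the run that produced them.
"""

from __future__ import annotations

import pandas as pd

from .breakpoints import InsertionCall
from .depth import CopyFoldEstimate, DepthProfile
from .svscan import LinkCluster, DepthDuplicationCall, Rejection


def _stamp(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# {parts}\n"


def write_tsv(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(meta))
        df.to_csv(fh, sep="\t", index=False)


def clusters_frame(clusters: list[LinkCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_a": c.contig_a,
                "start_a": c.interval_a[0],
                "end_a": c.interval_a[1],
                "contig_b": c.contig_b,
                "start_b": c.interval_b[0],
                "end_b": c.interval_b[1],
                "support": c.support,
                "mean_mapq": round(c.mean_mapq, 2),
                "split_support": c.split_support,
            }
            for c in clusters
        ]
    )


def rejections_frame(rejections: list[Rejection]) -> pd.DataFrame:
    rows = []
    for r in rejections:
        row = clusters_frame([r.cluster]).iloc[0].to_dict()
        row["reason"] = r.reason
        rows.append(row)
    return pd.DataFrame(rows)


def copyfold_frame(estimates: list[CopyFoldEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cassette_id": e.cassette_id,
                "contig": e.contig,
                "start": e.start,
                "end": e.end,
                "mean_depth": round(e.mean_depth, 3),
                "copy_fold": round(e.copy_fold, 3),
                "ci_low": round(e.ci[0], 3),
                "ci_high": round(e.ci[1], 3),
            }
            for e in estimates
        ]
    )


def write_insertion_vcf(
    call: InsertionCall,
    contig_lengths: dict[str, int],
    path: str,
    dup_calls: list[DepthDuplicationCall] | None = None,
    meta: dict | None = None,
) -> None:
    """Insertion call as paired BND records (+ DUP records for depth calls)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology sequence">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Interval end">',
        '##INFO=<ID=RC,Number=1,Type=Float,Description="Normalized read count">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Discordant pairs">',
        '##INFO=<ID=SPLIT,Number=1,Type=Integer,Description="Soft-clipped reads">',
    ]
    for name, ln in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={ln}>")
    if meta:
        for k, v in meta.items():
            lines.append(f"##{k}={v}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    lb, rb = call.left, call.right
    lmh, rmh = call.left_microhomology, call.right_microhomology
    lines.append(
        f"{lb.contig}\t{lb.coordinate}\tbnd_L\tN\tN[{rb.contig}:{rb.coordinate}[\t.\t"
        f"{'PASS' if lb.exact else 'IMPRECISE'}\t"
        f"SVTYPE=BND;MATEID=bnd_R;HOMLEN={lmh[1]};HOMSEQ={lmh[0] or '.'};"
        f"SUPPORT={lb.n_discordant};SPLIT={lb.n_softclip}"
    )
    lines.append(
        f"{rb.contig}\t{rb.coordinate}\tbnd_R\tN\t]{lb.contig}:{lb.coordinate}]N\t.\t"
        f"{'PASS' if rb.exact else 'IMPRECISE'}\t"
        f"SVTYPE=BND;MATEID=bnd_L;HOMLEN={rmh[1]};HOMSEQ={rmh[0] or '.'};"
        f"SUPPORT={rb.n_discordant};SPLIT={rb.n_softclip}"
    )
    for i, d in enumerate(dup_calls or []):
        lines.append(
            f"{d.contig}\t{d.start}\tdup_{i}\tN\t<DUP>\t.\tPASS\t"
            f"SVTYPE=DUP;END={d.end};RC={d.rc:.3f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_deletion_bed(call: InsertionCall, path: str, meta: dict | None = None) -> None:
    """Deleted interval as 0-based half-open BED (converter layer: internal
    coordinates are 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(_stamp(meta))
        # deleted bases are (left.coordinate, right.coordinate) exclusive
        fh.write(
            f"{call.contig}\t{call.left.coordinate}\t"
            f"{call.right.coordinate - 1}\tinsertion_site_deletion\n"
        )


def write_bedgraph(profile: DepthProfile, path: str, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(meta))
        for contig, (b0, depths) in sorted(profile.bins.items()):
            for i, d in enumerate(depths):
                start0 = b0 - 1 + i * profile.bin_width  # BED-style 0-based
                fh.write(f"{contig}\t{start0}\t{start0 + profile.bin_width}\t{d:.4f}\n")


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
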