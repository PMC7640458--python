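"""Independent brute-force recount of junction-spanning reads.

A deliberately naive, line-by-line text scan of a SAM file used as the
oracle against the pysam-based counting pipeline.  It shares no code with
the package: CIGAR strings are parsed with a regex and coordinates walked
in 1-based arithmetic.
"""

from __future__ import annotations

import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_OPS = set("MDN=X")


def scan_sam_text(
    path: str,
    catalogue: set[tuple[str, int, int]],
    min_anchor: int = 8,
    min_mapq: int = 0,
    gene_span: tuple[str, int, int] | None = None,
):
    """Recount junctions by scanning SAM text.

    Returns (counts dict keyed by (chrom, donor_end, acceptor_start),
    total_reads, gene_reads).
    """
    counts = {j: 0 for j in catalogue}
    total = 0
    gene_reads = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            flag, chrom, pos, mapq, cigar = (
                int(fields[1]), fields[2], int(fields[3]), int(fields[4]), fields[5],
            )
            if flag & 0x4:  # unmapped
                continue
            if flag & 0x100 or flag & 0x800:  # secondary / supplementary
                continue
            if flag & 0x400:  # duplicate
                continue
            if mapq < min_mapq:
                continue
            total += 1

            cur = pos  # 1-based next reference base to consume
            seg = 0
            segments = []
            junctions = []
            for num, op in _CIGAR_RE.findall(cigar):
                n = int(num)
                if op == "N":
                    junctions.append((chrom, cur - 1, cur + n))
                    segments.append(seg)
                    seg = 0
                elif op in _REF_OPS:
                    seg += n
                if op in _REF_OPS:
                    cur += n
            segments.append(seg)

            if gene_span is not None:
                g_chrom, g_start, g_end = gene_span
                if chrom == g_chrom and pos <= g_end and cur - 1 >= g_start:
                    gene_reads += 1

            for i, j in enumerate(junctions):
                if j in counts and segments[i] >= min_anchor and segments[i + 1] >= min_anchor:
                    counts[j] += 1
    return counts, total, gene_reads
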