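"""CpG-context / gene-context annotation, random-region generation, enrichment.

All intervals are 0-based half-open.  CpG context derives shores (0-2 kb
flank) and shelves (2-4 kb flank) geometrically from a merged island track,
with precedence island > shore > shelf, and partitions each query region's
length into fractional context coverage (island, shore, shelf, interCGI)
summing to 1.  Gene context is strand-aware: promoter = < 1 kb upstream of
the TSS, plus a 1-5 kb upstream window, 5'/3' UTRs, exons and introns;
regions touching none are intergenic.  Enrichment uses region-level
two-sided Fisher's exact tests against a matched random background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError

__all__ = [
    "EnrichmentResult",
    "merge_intervals",
    "annotate_cpg_context",
    "annotate_gene_context",
    "generate_random_regions",
    "fisher_enrichment",
    "chisq_annotation_fit",
    "CPG_CONTEXTS",
    "GENE_CONTEXTS",
]

CPG_CONTEXTS = ("island", "shore", "shelf", "interCGI")
GENE_CONTEXTS = ("upstream_1to5kb", "promoter", "utr5", "exon", "intron", "utr3", "intergenic")

SHORE_BP = 2_000
SHELF_BP = 2_000  # beyond the shore


class EnrichmentResult:
    """2x2 enrichment table with odds ratio and two-sided Fisher p."""

    def __init__(self, query_hits: int, query_misses: int,
                 bg_hits: int, bg_misses: int):
        if min(query_hits, query_misses, bg_hits, bg_misses) < 0:
            raise ValidationError("negative cell count")
        self.table = np.array([[query_hits, query_misses], [bg_hits, bg_misses]])
        if self.table.sum() == 0:
            raise ValidationError("empty enrichment table")
        _, self.p = stats.fisher_exact(self.table, alternative="two-sided")
        a, b, c, d = query_hits, query_misses, bg_hits, bg_misses
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane correction
        self.odds_ratio = (a * d) / (b * c)

    def __repr__(self) -> str:  # pragma: no cover
        return f"EnrichmentResult(OR={self.odds_ratio:.3g}, p={self.p:.3g})"


def merge_intervals(intervals):
    """Merge overlapping/adjacent (chrom, start, end) triples; sorted output."""
    by_chrom: dict[str, list] = {}
    for chrom, s, e in intervals:
        if s >= e:
            raise ValidationError(f"degenerate interval ({chrom},{s},{e})")
        by_chrom.setdefault(str(chrom), []).append((int(s), int(e)))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append((chrom, cs, ce))
                cs, ce = s, e
        out.append((chrom, cs, ce))
    return out


# ---------------------------------------------------------------------------
# CpG context
# ---------------------------------------------------------------------------

def annotate_cpg_context(regions, islands, genome: dict) -> pd.DataFrame:
    """Fractional CpG context per region over (island, shore, shelf, interCGI).

    Shores extend 0-2 kb on either side of each merged island and shelves
    2-4 kb, clipped at chromosome bounds, with precedence
    island > shore > shelf where derived zones overlap.  Each region's length
    is partitioned among the four contexts; fractions sum to 1.
    """
    islands = merge_intervals(islands)
    isl_by_chrom: dict[str, list] = {}
    for chrom, s, e in islands:
        isl_by_chrom.setdefault(chrom, []).append((s, e))

    rows = []
    for region in regions:
        chrom, start, end = str(region[0]), int(region[1]), int(region[2])
        if chrom not in genome:
            raise ValidationError(f"region on unknown chromosome {chrom!r}")
        if start < 0 or end > genome[chrom] or start >= end:
            raise ValidationError(f"region {region!r} outside genome extent")
        length = end - start
        cover = {k: 0 for k in CPG_CONTEXTS}
        # walk base intervals against island-derived zones with precedence
        ivs = isl_by_chrom.get(chrom, [])
        covered_island = _overlap_len(start, end, ivs)
        shore_ivs = merge_intervals(
            [(chrom, max(0, s - SHORE_BP), s) for s, _ in ivs if s > 0]
            + [(chrom, e, min(genome[chrom], e + SHORE_BP)) for _, e in ivs if e < genome[chrom]]
        ) if ivs else []
        shelf_ivs = merge_intervals(
            [(chrom, max(0, s - SHORE_BP - SHELF_BP), max(0, s - SHORE_BP)) for s, _ in ivs if s - SHORE_BP > 0]
            + [(chrom, min(genome[chrom], e + SHORE_BP), min(genome[chrom], e + SHORE_BP + SHELF_BP))
               for _, e in ivs if e + SHORE_BP < genome[chrom]]
        ) if ivs else []
        shore_only = _subtract([(s, e) for _, s, e in shore_ivs], ivs)
        shelf_only = _subtract(
            _subtract([(s, e) for _, s, e in shelf_ivs], ivs),
            shore_only,
        )
        cover["island"] = covered_island
        cover["shore"] = _overlap_len(start, end, shore_only)
        cover["shelf"] = _overlap_len(start, end, shelf_only)
        cover["interCGI"] = length - cover["island"] - cover["shore"] - cover["shelf"]
        rows.append({k: cover[k] / length for k in CPG_CONTEXTS})
    return pd.DataFrame(rows, index=[f"{r[0]}:{r[1]}-{r[2]}" for r in regions])


def _overlap_len(start: int, end: int, intervals) -> int:
    total = 0
    for s, e in intervals:
        total += max(0, min(end, e) - max(start, s))
    return total


def _subtract(intervals, minus):
    """Subtract interval list ``minus`` from ``intervals`` (both (s, e) lists)."""
    out = []
    for s, e in sorted(intervals):
        pieces = [(s, e)]
        for ms, me in sorted(minus):
            nxt = []
            for ps, pe in pieces:
                if me <= ps or ms >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < ms:
                    nxt.append((ps, ms))
                if me < pe:
                    nxt.append((me, pe))
            pieces = nxt
        out.extend(pieces)
    return [p for p in out if p[0] < p[1]]


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

def annotate_gene_context(regions, genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware gene-context labels per region (multi-label, else intergenic).

    ``genes`` needs columns chrom, start, end, strand, tss and may carry
    exon structure as a list column ``exons`` of (start, end) pairs; without
    exon structure the gene body beyond the UTR windows counts as intron.
    5'/3' UTRs default to the first/last 200 bp of the gene body when not
    given explicitly.
    """
    if "strand" not in genes.columns or genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValidationError("every gene record must carry a +/- strand")

    rows = []
    for region in regions:
        chrom, start, end = str(region[0]), int(region[1]), int(region[2])
        labels = {k: False for k in GENE_CONTEXTS}
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            tss = int(g["tss"])
            plus = g["strand"] == "+"
            promoter = (max(0, tss - 1000), tss) if plus else (tss, tss + 1000)
            upstream = (max(0, tss - 5000), max(0, tss - 1000)) if plus else (tss + 1000, tss + 5000)
            if _intersects(start, end, *promoter):
                labels["promoter"] = True
            if _intersects(start, end, *upstream):
                labels["upstream_1to5kb"] = True
            gs, ge = int(g["start"]), int(g["end"])
            if not _intersects(start, end, gs, ge):
                continue
            utr_len = int(g.get("utr_len", 200))
            utr5 = (gs, min(ge, gs + utr_len)) if plus else (max(gs, ge - utr_len), ge)
            utr3 = (max(gs, ge - utr_len), ge) if plus else (gs, min(ge, gs + utr_len))
            if _intersects(start, end, *utr5):
                labels["utr5"] = True
            if _intersects(start, end, *utr3):
                labels["utr3"] = True
            exons = g.get("exons", None)
            if isinstance(exons, (list, tuple)) and len(exons):
                in_exon = any(_intersects(start, end, int(s), int(e)) for s, e in exons)
                if in_exon:
                    labels["exon"] = True
                introns = _subtract([(gs, ge)], [(int(s), int(e)) for s, e in exons])
                if any(_intersects(start, end, s, e) for s, e in introns):
                    labels["intron"] = True
            else:
                body = _subtract([(gs, ge)], [utr5, utr3])
                if any(_intersects(start, end, s, e) for s, e in body):
                    labels["intron"] = True
        if not any(labels.values()):
            labels["intergenic"] = True
        rows.append(labels)
    return pd.DataFrame(rows, index=[f"{r[0]}:{r[1]}-{r[2]}" for r in regions])


def _intersects(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


# ---------------------------------------------------------------------------
# random background regions
# ---------------------------------------------------------------------------

def generate_random_regions(
    n: int, genome: dict, length_range=(50, 3100), seed: int = 0
) -> list:
    """Draw ``n`` random regions with lengths uniform on ``length_range``.

    Chromosomes are chosen with probability proportional to length, starts
    uniform within the chromosome; a draw that does not fit is resampled.
    Seeded and reproducible.
    """
    if n == 0:
        return []
    if not genome:
        raise ValidationError("empty genome extent")
    lo, hi = length_range
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    if lo > lengths.max():
        raise ValidationError("minimum region length exceeds the largest chromosome")
    rng = np.random.default_rng(seed)
    probs = lengths / lengths.sum()
    out = []
    while len(out) < n:
        c = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(lo, hi + 1))
        if length > genome[c]:
            continue  # resample
        start = int(rng.integers(0, genome[c] - length + 1))
        out.append((c, start, start + length))
    return out


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def fisher_enrichment(
    query, background, track, min_overlap_bp: int = 1
) -> EnrichmentResult:
    """Region-level enrichment of ``query`` vs ``background`` in ``track``.

    A region is a hit when it overlaps the track by >= ``min_overlap_bp``
    (default: a single base).  Two-sided Fisher's exact test on the 2x2
    hit/miss table; odds ratio with Haldane correction when a cell is 0.
    An empty track yields p = 1 with the odds ratio flagged NaN.
    """
    if not query or not background:
        raise ValidationError("query and background must both be nonempty")
    track = merge_intervals(track) if track else []
    if not track:
        res = EnrichmentResult(0, len(query), 0, len(background))
        res.odds_ratio = float("nan")
        return res
    by_chrom: dict[str, list] = {}
    for chrom, s, e in track:
        by_chrom.setdefault(chrom, []).append((s, e))

    def hit(region) -> bool:
        chrom, s, e = str(region[0]), int(region[1]), int(region[2])
        return _overlap_len(s, e, by_chrom.get(chrom, ())) >= min_overlap_bp

    qh = sum(hit(r) for r in query)
    bh = sum(hit(r) for r in background)
    return EnrichmentResult(qh, len(query) - qh, bh, len(background) - bh)


def chisq_annotation_fit(observed, background_props) -> tuple:
    """Pearson goodness-of-fit of observed context counts vs background proportions.

    ``observed`` is a count vector; ``background_props`` the expected
    proportions (rescaled to sum 1).  Categories with zero expected count are
    pooled into the nearest nonzero category with a warning.  Returns
    (X2, p, df).
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(background_props, dtype=float)
    if obs.shape != props.shape:
        raise ValidationError("observed and background have different lengths")
    if props.sum() <= 0:
        raise ValidationError("background proportions sum to zero")
    props = props / props.sum()
    zero = (props == 0) & (obs > 0)
    if zero.any():
        import warnings

        warnings.warn("zero-expectation categories pooled into the largest category")
        target = int(np.argmax(props))
        obs = obs.copy()
        obs[target] += obs[zero].sum()
        keep = ~zero
        obs, props = obs[keep], props[keep]
        props = props / props.sum()
    expected = props * obs.sum()
    keep = expected > 0
    obs, expected = obs[keep], expected[keep]
    x2 = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    return x2, p, df
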