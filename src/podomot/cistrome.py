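"""GR-binding-site (GBS) annotation against gene models.

Annotates ChIP-seq peak intervals relative to genes three ways:

* location class — intragenic (peak overlaps a gene's coding span),
  promoter (peak midpoint within 2.5 kb strictly upstream of a TSS,
  strand-aware, TSS excluded), or distal; intragenic takes precedence over
  promoter so the classes partition the peak set;
* gene-distance category — >50 kb from the coding span of any gene, or
  ≤50 kb from a glucocorticoid-responsive vs -unresponsive gene (nearest
  gene decides; an exact tie goes to the responsive gene);
* promoter enrichment — fraction of peak midpoints inside the merged 2.5 kb
  upstream promoter set of a gene subset, divided by that set's share of the
  genome (E = 1 means no enrichment over background).

All coordinates are 0-based half-open internally; BED is taken as-is and
GTF gene records (1-based inclusive) are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PROMOTER_BP",
    "GENE_DISTANCE_BP",
    "read_bed",
    "read_gene_table",
    "read_gtf_genes",
    "read_chrom_sizes",
    "load_intervals",
    "classify_location",
    "gene_distance_category",
    "annotate_peaks",
    "promoter_enrichment",
    "EnrichmentResult",
    "cistrome_summary",
]

PROMOTER_BP = 2_500
GENE_DISTANCE_BP = 50_000

LOCATION_CLASSES = ("intragenic", "promoter_2_5kb", "distal")
DISTANCE_CATEGORIES = ("gt50kb_any_gene", "le50kb_responsive", "le50kb_unresponsive")


# ---------------------------------------------------------------------------
# loading

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 peaks into a (chrom, start, end, name) frame."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split()
        if len(f) < 3:
            raise ValueError(f"malformed BED line {i + 1}: {line!r}")
        rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else f"peak_{i + 1}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError("BED intervals must satisfy 0 <= start < end")
    return df


def _finalize_genes(df: pd.DataFrame) -> pd.DataFrame:
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"malformed strand: {bad!r}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError("gene spans must satisfy 0 <= start < end")
    # strand-aware 5' end in 0-based coordinates
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df.reset_index(drop=True)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene table TSV: ``gene_id, chrom, start, end, strand, responsive``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end", "strand", "responsive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df["responsive"] = df["responsive"].astype(bool)
    return _finalize_genes(df)


def read_gtf_genes(path: str | Path, responsive_genes: set[str] | None = None) -> pd.DataFrame:
    """Extract ``gene`` features from a GTF (1-based inclusive -> half-open).

    *responsive_genes* marks members of the glucocorticoid-regulated list.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "gene":
            continue
        attrs = dict(
            (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
            for kv in f[8].rstrip(";").split(";") if kv.strip()
        )
        gene_id = attrs.get("gene_id", f"gene_{len(rows) + 1}")
        rows.append((gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    responsive_genes = responsive_genes or set()
    df["responsive"] = df["gene_id"].isin(responsive_genes)
    return _finalize_genes(df)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes TSV into {chrom: length}."""
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    return sizes


def load_intervals(
    peaks_bed: str | Path,
    genes: str | Path,
    chrom_sizes: str | Path,
    responsive_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Load peaks + gene models + genome table, validating chromosomes.

    *genes* may be a GTF (``.gtf``) or a gene-table TSV.
    """
    sizes = read_chrom_sizes(chrom_sizes)
    peaks = read_bed(peaks_bed)
    unknown = set(peaks["chrom"]) - set(sizes)
    if unknown:
        raise ValueError(f"peak on unknown chromosome(s): {sorted(unknown)}")
    if str(genes).endswith(".gtf"):
        gene_df = read_gtf_genes(genes, responsive_genes)
    else:
        gene_df = read_gene_table(genes)
    unknown = set(gene_df["chrom"]) - set(sizes)
    if unknown:
        raise ValueError(f"gene on unknown chromosome(s): {sorted(unknown)}")
    return peaks, gene_df, sizes


# ---------------------------------------------------------------------------
# classification

def _peak_mid(peaks: pd.DataFrame) -> np.ndarray:
    return (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2


def classify_location(
    peaks: pd.DataFrame, genes: pd.DataFrame, promoter_bp: int = PROMOTER_BP
) -> pd.DataFrame:
    """Location class and signed distance to the nearest TSS per peak.

    Precedence: any overlap with a gene span -> ``intragenic``; else midpoint
    within *promoter_bp* strictly upstream of a TSS -> ``promoter_2_5kb``;
    else ``distal``. TSS distance is midpoint-to-TSS, minimized over genes,
    signed strand-aware (upstream of the gene negative).
    """
    if genes.empty:
        raise ValueError("at least one gene model required")
    mids = _peak_mid(peaks)
    classes = np.full(len(peaks), "distal", dtype=object)
    dist = np.full(len(peaks), np.nan)
    nearest = np.full(len(peaks), "", dtype=object)
    for chrom, pidx in peaks.groupby("chrom").indices.items():
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        ps = peaks["start"].to_numpy()[pidx][:, None]
        pe = peaks["end"].to_numpy()[pidx][:, None]
        pm = mids[pidx][:, None]
        gs = g["start"].to_numpy()[None, :]
        ge = g["end"].to_numpy()[None, :]
        tss = g["tss"].to_numpy()[None, :]
        plus = (g["strand"].to_numpy() == "+")[None, :]

        overlap = (ps < ge) & (gs < pe)
        # signed midpoint-to-TSS distance, upstream negative
        signed = np.where(plus, pm - tss, tss - pm)
        j = np.argmin(np.abs(signed), axis=1)
        rows = np.arange(len(pidx))
        dist[pidx] = signed[rows, j]
        nearest[pidx] = g["gene_id"].to_numpy()[j]
        in_promoter = np.where(
            plus, (pm >= tss - promoter_bp) & (pm < tss),
            (pm > tss) & (pm <= tss + promoter_bp),
        )
        cls = np.where(
            overlap.any(axis=1), "intragenic",
            np.where(in_promoter.any(axis=1), "promoter_2_5kb", "distal"),
        )
        classes[pidx] = cls
    out = peaks[["name"]].copy()
    out["location_class"] = classes
    out["distance_to_nearest_tss"] = dist
    out["nearest_tss_gene"] = nearest
    return out


def _gene_gap_matrix(peaks: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Gap (bp) between each peak interval and each gene span; 0 if overlapping,
    inf across chromosomes."""
    gap = np.full((len(peaks), len(genes)), np.inf)
    same = peaks["chrom"].to_numpy()[:, None] == genes["chrom"].to_numpy()[None, :]
    ps = peaks["start"].to_numpy()[:, None]
    pe = peaks["end"].to_numpy()[:, None]
    gs = genes["start"].to_numpy()[None, :]
    ge = genes["end"].to_numpy()[None, :]
    g = np.maximum(0, np.maximum(gs - pe, ps - ge))
    gap[same] = g[same]
    return gap


def gene_distance_category(
    peaks: pd.DataFrame, genes: pd.DataFrame, max_distance_bp: int = GENE_DISTANCE_BP
) -> pd.DataFrame:
    """Three-way split by distance to gene coding spans.

    ``gt50kb_any_gene`` when the nearest gene span is > *max_distance_bp*
    away; otherwise the nearest gene's responsive flag decides the category,
    with an exact distance tie resolved toward the responsive gene.
    """
    if genes.empty:
        raise ValueError("at least one gene model required")
    gap = _gene_gap_matrix(peaks, genes)
    responsive = genes["responsive"].to_numpy()
    min_gap = gap.min(axis=1)
    # tie-break toward responsive genes: within the set attaining the minimum
    at_min = gap <= min_gap[:, None]
    near_responsive = (at_min & responsive[None, :]).any(axis=1)
    cat = np.where(
        min_gap > max_distance_bp, "gt50kb_any_gene",
        np.where(near_responsive, "le50kb_responsive", "le50kb_unresponsive"),
    )
    nearest_idx = np.argmin(np.where(at_min & responsive[None, :], gap - 0.5, gap), axis=1)
    out = peaks[["name"]].copy()
    out["gene_distance_category"] = cat
    out["gene_distance_bp"] = np.where(np.isinf(min_gap), np.nan, min_gap)
    out["nearest_gene"] = genes["gene_id"].to_numpy()[nearest_idx]
    return out


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_bp: int = PROMOTER_BP,
    max_distance_bp: int = GENE_DISTANCE_BP,
) -> pd.DataFrame:
    """Full per-peak annotation: location class + gene-distance category."""
    loc = classify_location(peaks, genes, promoter_bp)
    cat = gene_distance_category(peaks, genes, max_distance_bp)
    return loc.merge(cat, on="name")


# ---------------------------------------------------------------------------
# enrichment and summary

def _merged_promoters(
    genes: pd.DataFrame, sizes: dict[str, int], promoter_bp: int
) -> dict[str, np.ndarray]:
    """Merged strand-aware upstream promoter intervals per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            s, e = g["tss"] - promoter_bp, g["tss"]
        else:
            s, e = g["tss"] + 1, g["tss"] + 1 + promoter_bp
        s = max(0, s)
        e = min(sizes[g["chrom"]], e)
        if s < e:
            per_chrom.setdefault(g["chrom"], []).append((s, e))
    merged = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=int)
    return merged


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    observed_fraction: float    # peaks with midpoint in merged promoters / peaks
    background_fraction: float  # merged promoter bp / genome bp
    enrichment: float           # observed / background
    n_peaks_in_promoters: int
    promoter_bp: int


def promoter_enrichment(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    sizes: dict[str, int],
    label: str = "",
    promoter_bp: int = PROMOTER_BP,
) -> EnrichmentResult:
    """Enrichment of peak midpoints in the merged upstream promoter set
    of *genes* over the genome-wide background."""
    if peaks.empty:
        raise ValueError("empty peak set")
    merged = _merged_promoters(genes, sizes, promoter_bp)
    promoter_total = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in merged.values())
    genome_total = sum(sizes.values())
    if promoter_total == 0:
        raise ValueError("empty merged promoter set")
    mids = _peak_mid(peaks)
    hits = 0
    for chrom, pidx in peaks.groupby("chrom").indices.items():
        iv = merged.get(chrom)
        if iv is None:
            continue
        m = mids[pidx]
        inside = (m[:, None] >= iv[None, :, 0]) & (m[:, None] < iv[None, :, 1])
        hits += int(inside.any(axis=1).sum())
    obs = hits / len(peaks)
    bg = promoter_total / genome_total
    return EnrichmentResult(
        label=label, observed_fraction=obs, background_fraction=bg,
        enrichment=obs / bg, n_peaks_in_promoters=hits, promoter_bp=promoter_total,
    )


def cistrome_summary(
    annotations: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    max_distance_bp: int = GENE_DISTANCE_BP,
) -> dict:
    """Class/category fractions plus responsive-gene coverage.

    When *peaks* and *genes* are supplied, also counts the responsive genes
    that lie within *max_distance_bp* of at least one peak (each gene counted
    once), reporting numerator, denominator and percentage.
    """
    n = len(annotations)
    if n == 0:
        raise ValueError("no annotations")
    summary: dict = {
        "n_peaks": n,
        "location_class_fraction": {
            c: float((annotations["location_class"] == c).mean()) for c in LOCATION_CLASSES
        },
        "gene_distance_category_fraction": {
            c: float((annotations["gene_distance_category"] == c).mean())
            for c in DISTANCE_CATEGORIES
        },
    }
    if peaks is not None and genes is not None:
        resp = genes[genes["responsive"]].reset_index(drop=True)
        covered = 0
        if not resp.empty:
            gap = _gene_gap_matrix(peaks, resp)
            covered = int((gap.min(axis=0) <= max_distance_bp).sum())
        summary["responsive_genes_near_peak"] = {
            "numerator": covered,
            "denominator": int(len(resp)),
            "percent": 100.0 * covered / len(resp) if len(resp) else float("nan"),
        }
    return summary
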