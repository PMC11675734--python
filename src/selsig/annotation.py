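"""Candidate-SNP annotation: flanking windows, feature overlap, enrichment.

Each candidate SNP defines a window of ``flank`` bp (default 250 kb) on
either side of its position, clipped at the chromosome start.  User-supplied
gene/QTL features (BED or GFF3) hitting a window — inclusive-interval
intersection, 1-based coordinates — are collected per SNP and per term, and
term enrichment among the hit features is tested with a hypergeometric
upper tail against the whole annotation table (or the same-chromosome
subset), Bonferroni-corrected across the terms tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

_FEATURE_COLS = ["feature_id", "chrom", "start", "end", "feature_class", "term"]


@dataclass
class AnnotationTable:
    """Gene/QTL features: id, chromosome, 1-based inclusive span, class, term."""

    features: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.features
        missing = [c for c in _FEATURE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns {missing}")
        if (df["start"] > df["end"]).any():
            raise ValueError("feature start > end")
        self.features = df.reset_index(drop=True)

    @classmethod
    def from_bed(cls, path: str | Path, feature_class: str = "qtl") -> "AnnotationTable":
        """Read BED (0-based half-open): chrom start end name [term].

        The optional 5th column is the term label; otherwise the name is
        used.  Coordinates are converted to 1-based inclusive.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                name = f[3].strip() if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                term = f[4].strip() if len(f) > 4 else name
                rows.append((name, int(f[0].lstrip("chr") or 0),
                             int(f[1]) + 1, int(f[2]), feature_class, term))
        return cls(pd.DataFrame(rows, columns=_FEATURE_COLS))

    @classmethod
    def from_gff3(cls, path: str | Path, term_attribute: str = "Name",
                  feature_class: str = "gene") -> "AnnotationTable":
        """Read GFF3 (1-based inclusive); the term comes from an attribute."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                fid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
                term = attrs.get(term_attribute, fid)
                rows.append((fid, int(f[0].lstrip("chr") or 0),
                             int(f[3]), int(f[4]), f[2] or feature_class, term))
        return cls(pd.DataFrame(rows, columns=_FEATURE_COLS))

    def to_bed(self, path: str | Path) -> None:
        """Write as BED (converted to 0-based half-open)."""
        with open(path, "w") as fh:
            for _, r in self.features.iterrows():
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                         f"{r.feature_id}\t{r.term}\n")


def make_windows(snp_ids, marker_map: pd.DataFrame,
                 flank: int = 250_000) -> pd.DataFrame:
    """±flank bp windows around each SNP, 1-based inclusive, clipped at 1.

    Raises if any requested SNP is absent from the map.
    """
    marker_map = marker_map.set_index("snp_id")
    snp_ids = list(snp_ids)
    missing = [s for s in snp_ids if s not in marker_map.index]
    if missing:
        raise KeyError(f"SNPs absent from map: {sorted(missing)}")
    rows = []
    for s in snp_ids:
        chrom = int(marker_map.loc[s, "chrom"])
        pos = int(marker_map.loc[s, "pos"])
        rows.append((s, chrom, max(1, pos - flank), pos + flank))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "start", "end"])


def map_features(windows: pd.DataFrame, table: AnnotationTable) -> pd.DataFrame:
    """Features intersecting each window (inclusive convention).

    Returns one row per (snp, feature) hit with the overlap span.  Window
    chromosomes absent from the annotation produce zero hits.
    """
    hits = []
    feats = table.features
    for ch, wsub in windows.groupby("chrom"):
        fsub = feats[feats["chrom"] == ch]
        if fsub.empty:
            continue
        tree = IntervalTree()
        for i, r in fsub.iterrows():
            # half-open tree interval [start, end+1) == inclusive [start, end]
            tree.addi(int(r.start), int(r.end) + 1, i)
        for _, w in wsub.iterrows():
            for iv in sorted(tree.overlap(int(w.start), int(w.end) + 1)):
                r = feats.loc[iv.data]
                hits.append((
                    w.snp_id, r.feature_id, r.term, r.feature_class, int(ch),
                    max(int(w.start), int(r.start)),
                    min(int(w.end), int(r.end)),
                ))
    return pd.DataFrame(hits, columns=[
        "snp_id", "feature_id", "term", "feature_class", "chrom",
        "overlap_start", "overlap_end"])


def enrich(hits: pd.DataFrame, table: AnnotationTable,
           universe: str = "whole_table", alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term enrichment among hit features, Bonferroni-corrected.

    For each term with at least one hit: p = P(X >= observed) when drawing
    the number of distinct hit features from the universe (whole annotation
    table, or features on the chromosomes carrying hits when
    ``universe='same_chromosomes'``).
    """
    if universe not in ("whole_table", "same_chromosomes"):
        raise ValueError("unknown universe")
    if hits.empty:
        raise ValueError("no hits to test")
    feats = table.features
    if universe == "same_chromosomes":
        feats = feats[feats["chrom"].isin(set(hits["chrom"]))]
    hit_feats = hits.drop_duplicates("feature_id")
    M = len(feats)
    N = len(hit_feats)
    if N > M:
        raise ValueError("universe smaller than the hit set")
    rows = []
    terms = sorted(set(hit_feats["term"]))
    n_tested = len(terms)
    for term in terms:
        K = int((feats["term"] == term).sum())
        k = int((hit_feats["term"] == term).sum())
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        p_adj = min(1.0, p * n_tested)
        rows.append((term, k, K, p, p_adj, p_adj < alpha))
    df = pd.DataFrame(rows, columns=[
        "term", "observed", "background", "p_raw", "p_bonferroni",
        "significant"])
    return df.sort_values(["p_raw", "term"]).reset_index(drop=True)
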