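"""Fixed-difference sites, reference masking, and the 12-column allelic matrix.

Workflow at the variant level: filter a jointly genotyped VCF for biallelic
SNPs fixed for alternative alleles between the two parental populations,
mask those positions in the reference (so remapping carries no allele bias),
extract per-allele read depths (AD) into a parental + hybrid-allele count
matrix, annotate sites against gene models, and optionally aggregate site
counts to gene regions.

Coordinates: VCF and GTF/GFF are 1-based inclusive at the I/O boundary;
internal interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .nbcore import CountMatrix

logger = logging.getLogger(__name__)

ANNOTATION_CATEGORIES = ("exon", "UTR", "intron", "within_5kb", "intergenic")

__all__ = [
    "FixedDiffSite",
    "SiteAnnotation",
    "ANNOTATION_CATEGORIES",
    "call_fixed_differences",
    "mask_fasta",
    "build_allelic_matrix",
    "annotate_sites",
    "aggregate_to_genes",
]


@dataclass(frozen=True)
class FixedDiffSite:
    """Biallelic SNP fixed for the reference allele in population 1 and the
    alternative allele in population 2 (1-based position, as in the VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: tuple = field(default=(), compare=False)

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class SiteAnnotation:
    """Positional category of a site relative to gene models.

    Precedence: exon > UTR > intron > within_5kb > intergenic. ``within_5kb``
    means the site lies outside every gene span but within the window of at
    least one gene (both directions; strand labels direction only).
    """

    site_id: str
    category: str
    gene_ids: tuple = ()


_DNA = frozenset("ACGT")


def _sample_indices(vcf: VCF, sample_ids: list[str]) -> list[int]:
    missing = [s for s in sample_ids if s not in vcf.samples]
    if missing:
        raise KeyError(f"samples absent from VCF header: {missing}")
    return [vcf.samples.index(s) for s in sample_ids]


def call_fixed_differences(
    vcf_path, group1_samples: list[str], group2_samples: list[str]
) -> list[FixedDiffSite]:
    """Biallelic SNPs where every group-1 sample is homozygous reference and
    every group-2 sample homozygous alternative.

    Multiallelic records, indels, and sites with any heterozygous or missing
    genotype among the named parental samples are excluded. The returned set
    is invariant to record order and to sample-column order.
    """
    vcf = VCF(str(vcf_path))
    idx1 = _sample_indices(vcf, list(group1_samples))
    idx2 = _sample_indices(vcf, list(group2_samples))
    sites: list[FixedDiffSite] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _DNA or alt not in _DNA:
            continue
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        ok = all(gts[j][0] == 0 and gts[j][1] == 0 for j in idx1) and all(
            gts[j][0] == 1 and gts[j][1] == 1 for j in idx2
        )
        if ok:
            sites.append(
                FixedDiffSite(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=ref,
                    alt=alt,
                    genotypes=tuple((g[0], g[1]) for g in gts),
                )
            )
    vcf.close()
    return sites


def mask_fasta(
    fasta_in, fasta_out, sites: list[FixedDiffSite], *, line_width: int = 60
) -> None:
    """Replace the base at each site with 'N'; everything else unchanged.

    Sequence order and headers are preserved; line wrapping is normalized to
    ``line_width``. Idempotent: masking an already-masked reference is a
    no-op.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    fasta = Fasta(str(fasta_in), as_raw=True, sequence_always_upper=False)
    names = list(fasta.keys())
    for s in sites:
        if s.chrom not in fasta:
            raise KeyError(f"chromosome {s.chrom!r} not in reference (site {s.site_id})")
        if s.pos < 1 or s.pos > len(fasta[s.chrom]):
            raise ValueError(f"site {s.site_id} outside sequence of length {len(fasta[s.chrom])}")
    with open(fasta_out, "w") as out:
        for name in names:
            seq = list(str(fasta[name][:]))
            for pos in by_chrom.get(name, ()):
                seq[pos - 1] = "N"
            out.write(f">{name}\n")
            text = "".join(seq)
            for start in range(0, len(text), line_width):
                out.write(text[start : start + line_width] + "\n")
    fasta.close()


def build_allelic_matrix(
    vcf_path,
    sites: list[FixedDiffSite],
    group1_samples: list[str],
    group2_samples: list[str],
    hybrid_samples: list[str],
    *,
    group1_label: str = "AUS",
    group2_label: str = "TIM",
    hybrid_label: str = "HYB",
) -> CountMatrix:
    """Per-site allele-depth matrix: one column per parental sample, two per
    hybrid.

    Each parental column holds that sample's depth of its population's fixed
    allele (reference-allele depth for group 1, alternative for group 2);
    hybrid columns hold the group-1-allele depth (allele A) and the
    group-2-allele depth (allele B). Allele polarity is by population of
    origin, which at fixed-difference sites coincides with REF/ALT. Sites
    with any missing AD value are dropped and logged, never imputed.
    """
    vcf = VCF(str(vcf_path))
    idx1 = _sample_indices(vcf, list(group1_samples))
    idx2 = _sample_indices(vcf, list(group2_samples))
    idxh = _sample_indices(vcf, list(hybrid_samples))
    wanted = {(s.chrom, s.pos) for s in sites}

    cols: list[str] = list(group1_samples) + list(group2_samples)
    meta_rows = [(group1_label, "P", "A", s) for s in group1_samples]
    meta_rows += [(group2_label, "P", "B", s) for s in group2_samples]
    for s in hybrid_samples:
        cols += [f"{s}_A", f"{s}_B"]
        meta_rows += [(hybrid_label, "H", "A", s), (hybrid_label, "H", "B", s)]
    meta = pd.DataFrame(
        meta_rows, columns=["population", "type", "allele", "sample"], index=cols
    )

    row_ids, rows = [], []
    n_dropped = 0
    for var in vcf:
        key = (var.CHROM, var.POS)
        if key not in wanted:
            continue
        ad = var.format("AD")
        if ad is None:
            n_dropped += 1
            logger.warning("site %s:%d dropped: no AD field", *key)
            continue
        ad = np.asarray(ad)
        needed = idx1 + idx2 + idxh
        if np.any(ad[needed, :2] < 0):  # cyvcf2 encodes missing as negative
            n_dropped += 1
            logger.warning("site %s:%d dropped: missing allelic depth", *key)
            continue
        row = [int(ad[j, 0]) for j in idx1] + [int(ad[j, 1]) for j in idx2]
        for j in idxh:
            row += [int(ad[j, 0]), int(ad[j, 1])]
        row_ids.append(f"{var.CHROM}:{var.POS}")
        rows.append(row)
    vcf.close()
    if n_dropped:
        logger.info("build_allelic_matrix: dropped %d sites with missing depths", n_dropped)
    frame = pd.DataFrame(rows, index=pd.Index(row_ids, name="feature"), columns=cols, dtype=np.int64)
    return CountMatrix(frame, meta)


# ---------------------------------------------------------------------------
# annotation against gene models
# ---------------------------------------------------------------------------


def _load_gene_models(gene_models_path):
    import gffutils

    return gffutils.create_db(
        str(gene_models_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )


def _check_interval(feat) -> tuple[int, int]:
    if feat.end < feat.start:
        raise ValueError(
            f"malformed interval {feat.seqid}:{feat.start}-{feat.end} ({feat.featuretype})"
        )
    return feat.start - 1, feat.end  # 1-based inclusive -> 0-based half-open


def annotate_sites(
    sites: list[FixedDiffSite], gene_models_path, *, window: int = 5000
) -> list[SiteAnnotation]:
    """Assign each site a positional category and associated gene ids.

    Precedence exon > UTR > intron > within_5kb > intergenic. A site inside a
    gene span that overlaps no exon/UTR/intron feature (an annotation gap) is
    categorised intron, since the category set has no other genic level and
    ``within_5kb`` requires the site to lie outside all gene spans. The
    window applies up- and downstream alike; strand is not used for
    inclusion.
    """
    db = _load_gene_models(gene_models_path)
    trees: dict[str, dict[str, IntervalTree]] = {}
    gene_spans: dict[str, IntervalTree] = {}

    def _tree(chrom: str, kind: str) -> IntervalTree:
        return trees.setdefault(chrom, {}).setdefault(kind, IntervalTree())

    def _gene_of(feat) -> str | None:
        for key in ("gene_id", "Parent", "gene"):
            if key in feat.attributes:
                return feat.attributes[key][0]
        return None

    for gene in db.features_of_type("gene"):
        start, end = _check_interval(gene)
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        gene_spans.setdefault(gene.seqid, IntervalTree()).addi(start, end, gid)

    utr_types = [t for t in db.featuretypes() if "utr" in t.lower()]
    for kind_out, kinds_in in (("exon", ["exon"]), ("UTR", utr_types)):
        for kind in kinds_in:
            for feat in db.features_of_type(kind):
                start, end = _check_interval(feat)
                gid = _gene_of(feat)
                _tree(feat.seqid, kind_out).addi(start, end, gid)

    # introns: gaps between consecutive exons of each transcript
    for tx_type in ("transcript", "mRNA"):
        for tx in db.features_of_type(tx_type):
            exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
            gid = _gene_of(tx)
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end + 1:
                    _tree(tx.seqid, "intron").addi(a.end, b.start - 1, gid)

    out: list[SiteAnnotation] = []
    for site in sites:
        p0 = site.pos - 1  # 0-based
        chrom_trees = trees.get(site.chrom, {})
        category, genes = None, ()
        for kind in ("exon", "UTR", "intron"):
            hits = chrom_trees.get(kind, IntervalTree())[p0]
            if hits:
                category = kind
                genes = tuple(sorted({h.data for h in hits if h.data}))
                break
        if category is None:
            spans = gene_spans.get(site.chrom, IntervalTree())
            inside = spans[p0]
            if inside:
                category = "intron"
                genes = tuple(sorted({h.data for h in inside}))
            else:
                near = spans[max(p0 - window, 0) : p0 + window + 1]
                if near:
                    category = "within_5kb"
                    genes = tuple(sorted({h.data for h in near}))
                else:
                    category, genes = "intergenic", ()
        out.append(SiteAnnotation(site_id=site.site_id, category=category, gene_ids=genes))
    return out


def aggregate_to_genes(
    matrix: CountMatrix, annotations: list[SiteAnnotation]
) -> CountMatrix:
    """Column-wise sum of site counts per associated gene.

    Sites associated with several genes contribute to each (logged);
    intergenic / gene-less sites are excluded.
    """
    by_site = {a.site_id: a for a in annotations}
    missing = [fid for fid in matrix.feature_ids if fid not in by_site]
    if missing:
        raise KeyError(f"annotations missing for {len(missing)} sites (e.g. {missing[0]!r})")
    gene_rows: dict[str, np.ndarray] = {}
    n_multi = 0
    for fid in matrix.feature_ids:
        ann = by_site[fid]
        if not ann.gene_ids:
            continue
        if len(ann.gene_ids) > 1:
            n_multi += 1
        row = matrix.counts.loc[fid].to_numpy()
        for gid in ann.gene_ids:
            if gid in gene_rows:
                gene_rows[gid] = gene_rows[gid] + row
            else:
                gene_rows[gid] = row.copy()
    if n_multi:
        logger.info("aggregate_to_genes: %d sites shared by multiple genes (double-counted)", n_multi)
    frame = pd.DataFrame.from_dict(gene_rows, orient="index", columns=matrix.column_ids)
    frame.index.name = "feature"
    frame = frame.sort_index()
    return CountMatrix(frame.astype(np.int64), matrix.col_meta)
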