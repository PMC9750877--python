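"""Assignment hierarchy (against an independent interval oracle), UFI
propagation, molecule counting, terminal restriction and intronic fraction."""

import numpy as np
import pandas as pd
import pytest

from sctotal import feature_counting as fc
from sctotal.feature_counting import (
    AlignedRead,
    Assignment,
    DISCARDED,
    Gene,
    GeneAnnotation,
    SMALL_RNA_BIOTYPES,
    UNASSIGNED,
    assign_read,
)

from conftest import toy_gene


def read_at(blocks, strand="+", chrom="chr1"):
    return AlignedRead("CELL", "UFIUFI", chrom, strand, tuple(blocks))


# ---------------------------------------------------------------------------
# independent brute-force oracle for rules 1-4 (interval arithmetic only)


def oracle_assign(read: AlignedRead, genes: list[Gene], strand_mode="same"):
    def overlaps(iv, jv):
        return iv[0] < jv[1] and iv[1] > jv[0]

    cands = []
    for g in genes:
        if g.chrom != read.chrom:
            continue
        if strand_mode == "same" and g.strand != read.strand:
            continue
        if any(overlaps(b, (g.start, g.end)) for b in read.blocks):
            cands.append(g)
    if not cands:
        return (UNASSIGNED, "not_applicable")
    if any(g.biotype == "TEC" for g in cands):
        return (DISCARDED, "not_applicable")
    small = [
        g
        for g in cands
        if g.biotype in SMALL_RNA_BIOTYPES
        and all(g.start <= b[0] and b[1] <= g.end for b in read.blocks)
    ]
    if small:
        if len(small) == 1:
            return (small[0].gene_id, "not_applicable")
        return ("–".join(sorted(g.name for g in small)), "not_applicable")
    genic = [g for g in cands if g.biotype not in SMALL_RNA_BIOTYPES]
    if not genic:
        return (UNASSIGNED, "not_applicable")
    exonic = []
    for g in genic:
        if all(any(s <= b[0] and b[1] <= e for s, e in g.exons) for b in read.blocks):
            exonic.append(g)
    hits, status = (exonic, "spliced") if exonic else (genic, "unspliced")
    if len(hits) == 1:
        return (hits[0].gene_id, status)
    return ("–".join(sorted(g.name for g in hits)), status)


class TestHierarchy:
    def test_tec_contact_discards(self, annotation):
        tec = next(g for g in annotation.genes.values() if g.biotype == "TEC")
        r = read_at([(tec.start + 10, tec.start + 70)], strand=tec.strand, chrom=tec.chrom)
        assert assign_read(r, annotation).feature == DISCARDED

    def test_nested_snorna_captures_fully_contained_read(self, annotation):
        sno = annotation.genes["moSNO0"]
        r = read_at([(sno.start + 10, sno.start + 70)], strand=sno.strand, chrom=sno.chrom)
        a = assign_read(r, annotation)
        assert a.feature == "moSNO0" and a.status == "not_applicable"

    def test_partial_snorna_overlap_falls_through_to_host_intron(self, annotation):
        sno = annotation.genes["moSNO0"]
        host = annotation.genes["moPCA"]
        r = read_at([(sno.start - 30, sno.start + 30)], strand=sno.strand, chrom=sno.chrom)
        a = assign_read(r, annotation)
        assert a.feature == host.gene_id and a.status == "unspliced"

    def test_exon_intron_junction_is_unspliced(self):
        gene = toy_gene(exons=((100, 200), (300, 400)))
        ann = GeneAnnotation([gene])
        a = assign_read(read_at([(190, 310)]), ann)
        assert a == Assignment("G1", "unspliced", "protein_coding")

    def test_read_inside_exon_is_spliced(self):
        ann = GeneAnnotation([toy_gene(exons=((100, 200), (300, 400)))])
        a = assign_read(read_at([(120, 180)]), ann)
        assert a == Assignment("G1", "spliced", "protein_coding")

    def test_exon_exon_junction_read_is_spliced(self):
        ann = GeneAnnotation([toy_gene(exons=((100, 200), (300, 400)))])
        a = assign_read(read_at([(170, 200), (300, 330)]), ann)
        assert a.status == "spliced"

    def test_overlapping_exonic_genes_give_composite_name(self):
        a = toy_gene("GA", exons=((100, 300),))
        b = toy_gene("GB", exons=((200, 400),))
        ann = GeneAnnotation([a, b])
        res = assign_read(read_at([(220, 280)]), ann)
        assert res.feature == "ga–gb" and res.status == "spliced"
        assert res.biotype == "composite"

    def test_exonic_hit_preferred_over_intronic(self):
        outer = toy_gene("OUT", exons=((0, 100), (1000, 1100)))
        inner = toy_gene("INN", exons=((300, 500),))
        ann = GeneAnnotation([outer, inner])
        res = assign_read(read_at([(350, 410)]), ann)
        assert res.feature == "INN" and res.status == "spliced"

    def test_antisense_read_is_unassigned_in_same_strand_mode(self):
        ann = GeneAnnotation([toy_gene(strand="+")])
        assert assign_read(read_at([(120, 180)], strand="-"), ann).feature == UNASSIGNED
        assert (
            assign_read(read_at([(120, 180)], strand="-"), ann, strand_mode="ignore").feature
            == "G1"
        )

    def test_matches_oracle_on_random_reads(self, annotation):
        genes = list(annotation.genes.values())
        rng = np.random.default_rng(0)
        span_lo = min(g.start for g in genes if g.chrom == "mouse_chr1")
        span_hi = max(g.end for g in genes if g.chrom == "mouse_chr1")
        for _ in range(1000):
            start = int(rng.integers(span_lo - 200, span_hi + 200))
            length = int(rng.integers(20, 150))
            if rng.random() < 0.2:  # occasional two-block read
                gap = int(rng.integers(50, 400))
                blocks = [(start, start + length), (start + length + gap, start + length + gap + 40)]
            else:
                blocks = [(start, start + length)]
            r = read_at(blocks, strand="+" if rng.random() < 0.5 else "-", chrom="mouse_chr1")
            got = assign_read(r, annotation)
            assert (got.feature, got.status) == oracle_assign(r, genes)

    def test_assignment_invariant_to_annotation_record_order(self, annotation):
        genes = list(annotation.genes.values())
        shuffled = GeneAnnotation(list(reversed(genes)))
        rng = np.random.default_rng(1)
        for _ in range(100):
            start = int(rng.integers(0, 40000))
            r = read_at([(start, start + 60)], strand="+", chrom="mouse_chr1")
            a1, a2 = assign_read(r, annotation), assign_read(r, shuffled)
            assert (a1.feature, a1.status) == (a2.feature, a2.status)


class TestDepletion:
    def test_read_inside_rrna_removed_and_outside_retained(self, annotation):
        rrna = next(g for g in annotation.genes.values() if g.biotype == "rRNA")
        inside = {"barcode": "c", "ufi": "u", "chrom": rrna.chrom, "strand": "+",
                  "blocks": ((rrna.start + 5, rrna.start + 65),), "read_id": "r0"}
        outside = dict(inside, blocks=((rrna.end + 100, rrna.end + 160),), read_id="r1")
        reads = pd.DataFrame([inside, outside])
        survivors, report = fc.deplete_rrna(reads, annotation.rrna_intervals())
        assert report == {"input": 2, "removed": 1, "retained": 1}
        assert list(survivors["read_id"]) == ["r1"]

    def test_depletion_report_equals_planted_rrna_reads(self, reads_and_truth, annotation):
        reads, truth = reads_and_truth
        _, report = fc.deplete_rrna(reads, annotation.rrna_intervals())
        assert report["removed"] == truth.n_rrna_reads


class TestPropagation:
    def test_mixed_group_becomes_all_unspliced(self):
        df = pd.DataFrame(
            {
                "barcode": ["c"] * 2,
                "feature": ["G"] * 2,
                "ufi": ["U"] * 2,
                "status": ["spliced", "unspliced"],
            }
        )
        out = fc.propagate_unspliced(df)
        assert list(out["status"]) == ["unspliced", "unspliced"]

    def test_all_spliced_group_unchanged(self):
        df = pd.DataFrame(
            {"barcode": ["c"] * 2, "feature": ["G"] * 2, "ufi": ["U"] * 2,
             "status": ["spliced", "spliced"]}
        )
        assert list(fc.propagate_unspliced(df)["status"]) == ["spliced", "spliced"]

    def test_matches_any_unspliced_brute_force_on_random_groups(self):
        rng = np.random.default_rng(2)
        n_groups = 10_000
        rows = []
        for g in range(n_groups):
            size = int(rng.integers(1, 5))
            for _ in range(size):
                rows.append(
                    (
                        f"c{g % 50}",
                        f"G{g % 200}",
                        f"U{g}",
                        "unspliced" if rng.random() < 0.3 else "spliced",
                    )
                )
        df = pd.DataFrame(rows, columns=["barcode", "feature", "ufi", "status"])
        out = fc.propagate_unspliced(df)
        # oracle: per-group any-unspliced scan
        expected = {}
        for row in df.itertuples(index=False):
            key = (row.barcode, row.feature, row.ufi)
            expected[key] = expected.get(key, False) or row.status == "unspliced"
        for row in out.itertuples(index=False):
            want = "unspliced" if expected[(row.barcode, row.feature, row.ufi)] else "spliced"
            assert row.status == want
        groups = out.groupby(["barcode", "feature", "ufi"])["status"].nunique()
        assert (groups == 1).all()


class TestCounting:
    def test_one_group_of_five_reads_is_one_molecule(self):
        ann = GeneAnnotation([toy_gene()])
        df = pd.DataFrame(
            {"barcode": ["c"] * 5, "feature": ["G1"] * 5, "ufi": ["U"] * 5,
             "status": ["unspliced"] * 5}
        )
        mat = fc.count_molecules(df, ann, cells=["c"])
        assert mat.layers["unspliced"][0, 0] == 1
        assert mat.layers["spliced"][0, 0] == 0

    def test_empty_stream_gives_zero_matrix_with_full_feature_index(self, annotation):
        df = pd.DataFrame(columns=["barcode", "feature", "ufi", "status"])
        mat = fc.count_molecules(df, annotation, cells=["c1"])
        assert mat.n_vars == len(annotation)
        assert mat.X.sum() == 0

    def test_matrix_equals_ground_truth_molecules_exactly(self, count_matrix):
        mat, truth = count_matrix
        gt = truth.molecules
        for status, layer in (("unspliced", "unspliced"),):
            want = (
                gt[gt["status"] == status]
                .groupby(["cell", "gene"])
                .size()
                .unstack(fill_value=0)
                .reindex(index=mat.obs_names, columns=mat.var_names, fill_value=0)
            )
            got = pd.DataFrame(
                np.asarray(mat.layers[layer]), index=mat.obs_names, columns=mat.var_names
            )
            assert (got.values == want.values).all()
        want_total = (
            gt.groupby(["cell", "gene"]).size().unstack(fill_value=0)
            .reindex(index=mat.obs_names, columns=mat.var_names, fill_value=0)
        )
        assert (np.asarray(mat.X) == want_total.values).all()

    def test_layer_sums_equal_total_molecules(self, count_matrix):
        mat, truth = count_matrix
        total = mat.layers["spliced"].sum() + mat.layers["unspliced"].sum()
        assert total == mat.X.sum() == len(truth.molecules)
        per_cell = (
            mat.layers["spliced"].sum(axis=1) + mat.layers["unspliced"].sum(axis=1)
        )
        assert (per_cell == np.asarray(mat.X.sum(axis=1)).ravel()).all()


class TestTerminalRestriction:
    def _frame(self, blocks_list):
        return pd.DataFrame(
            {
                "barcode": ["c"] * len(blocks_list),
                "ufi": [f"U{i}" for i in range(len(blocks_list))],
                "feature": ["G1"] * len(blocks_list),
                "status": ["spliced"] * len(blocks_list),
                "blocks": blocks_list,
            }
        )

    def test_plus_strand_keeps_terminal_window(self):
        gene = toy_gene(exons=((0, 1000),))
        ann = GeneAnnotation([gene])
        df = self._frame([((700, 780),), ((850, 930),)])  # midpoints 740, 890
        out = fc.restrict_terminal(df, ann, terminal_fraction=0.2)
        assert list(out["ufi"]) == ["U1"]

    def test_minus_strand_window_is_at_low_coordinates(self):
        gene = toy_gene(exons=((0, 1000),), strand="-")
        ann = GeneAnnotation([gene])
        df = self._frame([((100, 180),), ((850, 930),)])
        out = fc.restrict_terminal(df, ann, terminal_fraction=0.2)
        assert list(out["ufi"]) == ["U0"]

    def test_fraction_one_is_identity(self, assigned_reads, annotation):
        assigned, _ = assigned_reads
        out = fc.restrict_terminal(assigned, annotation, terminal_fraction=1.0)
        assert len(out) == len(assigned)

    def test_window_uses_spliced_coordinates(self):
        # two 500-nt exons with a large intron: genomic midpoint of the
        # second exon is deep in the gene, but exonically it is terminal
        gene = toy_gene(exons=((0, 500), (10_000, 10_500)))
        ann = GeneAnnotation([gene])
        df = self._frame([((10_300, 10_360),)])  # exonic midpoint 830 of 1000
        out = fc.restrict_terminal(df, ann, terminal_fraction=0.2)
        assert len(out) == 1
        out2 = fc.restrict_terminal(df, ann, terminal_fraction=0.1)
        assert len(out2) == 0


class TestIntronicFraction:
    def test_simple_ratio(self):
        import anndata as ad

        adata = ad.AnnData(
            X=np.array([[100.0]]),
            layers={"spliced": np.array([[60]]), "unspliced": np.array([[40]])},
            var=pd.DataFrame({"biotype": ["protein_coding"]}, index=["G1"]),
        )
        assert fc.intronic_fraction(adata).iloc[0] == pytest.approx(0.40)

    def test_all_spliced_gives_zero(self):
        import anndata as ad

        adata = ad.AnnData(
            X=np.array([[5.0]]),
            layers={"spliced": np.array([[5]]), "unspliced": np.array([[0]])},
            var=pd.DataFrame({"biotype": ["protein_coding"]}, index=["G1"]),
        )
        assert fc.intronic_fraction(adata).iloc[0] == 0.0

    def test_planted_unspliced_fraction_recovered(self, count_matrix, small_config):
        mat, _ = count_matrix
        frac = fc.intronic_fraction(mat)
        assert abs(frac.mean() - small_config.unspliced_fraction) <= 0.02
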