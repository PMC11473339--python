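"""Provenance classification: locus matrix, class rules, Venn counts."""

import numpy as np
import pandas as pd
import pytest

from chimeraems.config import SimulationConfig
from chimeraems.errors import InputError
from chimeraems.provenance import (
    CLASS_AMBIGUOUS,
    CLASS_BACKGROUND,
    CLASS_EMS1,
    CLASS_EMS2,
    CLASS_UNRESOLVED,
    REASON_CONFLICT,
    REASON_CROSS_LINE,
    REASON_UNCALLABLE,
    REF_CALLABLE,
    UNCALLABLE,
    SampleSheet,
    build_locus_matrix,
    classify_locus,
    partition,
)
from conftest import run_simulation

S = ("GY1Y", "GY1G", "GY2Y", "GY2G")


def _pattern(**kw):
    base = {s: REF_CALLABLE for s in S}
    base.update(kw)
    return base


class TestSampleSheet:
    def test_missing_sector_rejected(self):
        with pytest.raises(InputError, match="yellow"):
            SampleSheet(
                pd.DataFrame(
                    {"sample": ["a"], "line": ["L1"], "sector": ["yellow"]}
                )
            )

    def test_duplicate_line_sector_rejected(self):
        with pytest.raises(InputError):
            SampleSheet(
                pd.DataFrame(
                    {
                        "sample": ["a", "b"],
                        "line": ["L1", "L1"],
                        "sector": ["yellow", "yellow"],
                    }
                )
            )


class TestClassifyLocus:
    def test_background_when_all_samples_share_allele(self, four_sample_sheet):
        cl = classify_locus(_pattern(GY1Y="T", GY1G="T", GY2Y="T", GY2G="T"),
                            four_sample_sheet)
        assert cl.label == CLASS_BACKGROUND

    def test_first_round_when_one_line_shares(self, four_sample_sheet):
        cl = classify_locus(_pattern(GY1Y="C", GY1G="C"), four_sample_sheet)
        assert (cl.label, cl.line) == (CLASS_EMS1, "GY1")

    def test_second_round_when_one_sample_unique(self, four_sample_sheet):
        cl = classify_locus(_pattern(GY1Y="G"), four_sample_sheet)
        assert (cl.label, cl.line, cl.sector) == (CLASS_EMS2, "GY1", "yellow")

    def test_cross_line_sharing_is_ambiguous(self, four_sample_sheet):
        cl = classify_locus(_pattern(GY1Y="A", GY2G="A"), four_sample_sheet)
        assert (cl.label, cl.reason) == (CLASS_AMBIGUOUS, REASON_CROSS_LINE)

    def test_absence_resting_on_uncallable_is_ambiguous(self, four_sample_sheet):
        cl = classify_locus(
            _pattern(GY1Y="A", GY2Y=UNCALLABLE), four_sample_sheet
        )
        assert (cl.label, cl.reason) == (CLASS_AMBIGUOUS, REASON_UNCALLABLE)

    def test_conflicting_alleles_are_ambiguous(self, four_sample_sheet):
        cl = classify_locus(
            _pattern(GY1Y="A", GY1G="T", GY2Y="A", GY2G="A"), four_sample_sheet
        )
        assert (cl.label, cl.reason) == (CLASS_AMBIGUOUS, REASON_CONFLICT)

    def test_single_line_shared_is_unresolved(self):
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample": ["Y", "G"],
                    "line": ["L1", "L1"],
                    "sector": ["yellow", "green"],
                }
            )
        )
        cl = classify_locus({"Y": "T", "G": "T"}, sheet)
        assert cl.label == CLASS_UNRESOLVED


class TestLocusMatrix:
    def _calls(self, sample, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt"]
        ).assign(sample=sample)

    def test_states_from_mask_depths(self, four_sample_sheet):
        calls = {"GY1Y": self._calls("GY1Y", [("chr1", 100, "C", "T")])}
        masks = {
            s: pd.DataFrame({"chrom": ["chr1"], "pos": [100], "depth": [d]})
            for s, d in zip(S, (30, 30, 30, 2))
        }
        m = build_locus_matrix(calls, masks, four_sample_sheet)
        row = m.iloc[0]
        assert row["GY1Y"] == "T"
        assert row["GY1G"] == REF_CALLABLE and row["GY2Y"] == REF_CALLABLE
        assert row["GY2G"] == UNCALLABLE  # depth below the callability floor

    def test_row_count_is_union_of_call_positions(self, four_sample_sheet):
        rng = np.random.default_rng(0)
        calls = {}
        truth_union = set()
        for s in S:
            pos = rng.choice(np.arange(1, 500), size=60, replace=False)
            calls[s] = self._calls(s, [("chr1", int(p), "C", "T") for p in pos])
            truth_union |= {int(p) for p in pos}
        m = build_locus_matrix(calls, None, four_sample_sheet)
        assert len(m) == len(truth_union)

    def test_unknown_sample_rejected(self, four_sample_sheet):
        with pytest.raises(InputError, match="mystery"):
            build_locus_matrix(
                {"mystery": self._calls("mystery", [("chr1", 1, "A", "T")])},
                None,
                four_sample_sheet,
            )

    def test_empty_input_gives_empty_partition(self, four_sample_sheet):
        m = build_locus_matrix({s: self._calls(s, []) for s in S}, None,
                               four_sample_sheet)
        result = partition(m, four_sample_sheet)
        assert result.n_loci == 0
        assert (result.venn["count"] == 0).all()


class TestPartition:
    def _toy_matrix(self):
        # 1 background, 1 EMS1 per line, 1 unique per yellow sample, 1 ambiguous
        rows = [
            ("chr1", 10, "C", "T", "T", "T", "T"),
            ("chr1", 20, "G", "A", "A", REF_CALLABLE, REF_CALLABLE),
            ("chr1", 30, "G", REF_CALLABLE, REF_CALLABLE, "A", "A"),
            ("chr1", 40, "C", "T", REF_CALLABLE, REF_CALLABLE, REF_CALLABLE),
            ("chr1", 50, "C", REF_CALLABLE, REF_CALLABLE, "T", REF_CALLABLE),
            ("chr1", 60, "C", "T", REF_CALLABLE, "T", REF_CALLABLE),
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", *S])

    def test_toy_venn_counts(self, four_sample_sheet):
        result = partition(self._toy_matrix(), four_sample_sheet)
        venn = result.venn.set_index("cell")["count"]
        assert venn["shared_all"] == 1
        assert venn["shared_GY1"] == 1 and venn["shared_GY2"] == 1
        assert venn["unique_GY1Y"] == 1 and venn["unique_GY2Y"] == 1
        assert venn["unique_GY1G"] == 0 and venn["unique_GY2G"] == 0
        assert venn["ambiguous"] == 1

    def test_counts_conserve_total(self, four_sample_sheet):
        result = partition(self._toy_matrix(), four_sample_sheet)
        assert result.venn["count"].sum() == result.n_loci

    def test_locus_order_does_not_change_counts(self, four_sample_sheet):
        m = self._toy_matrix()
        shuffled = m.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = partition(m, four_sample_sheet).venn
        b = partition(shuffled, four_sample_sheet).venn
        pd.testing.assert_frame_equal(a, b)

    def test_swapping_line_labels_permutes_counts(self, four_sample_sheet):
        m = self._toy_matrix()
        swapped_sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample": list(S),
                    "line": ["GY2", "GY2", "GY1", "GY1"],
                    "sector": ["yellow", "green", "yellow", "green"],
                }
            )
        )
        a = partition(m, four_sample_sheet).venn.set_index("cell")["count"]
        b = partition(m, swapped_sheet).venn.set_index("cell")["count"]
        assert a["shared_GY1"] == b["shared_GY2"]
        assert a["unique_GY1Y"] == b["unique_GY1Y"]  # cells keyed by sample
        assert a["shared_all"] == b["shared_all"]

    def test_zero_noise_partition_equals_truth(self, recovery_run):
        truth = recovery_run["truth"].variants.set_index(["chrom", "pos"])
        loci = recovery_run["partition"].loci
        assert len(loci) == len(truth)
        for rec in loci.itertuples():
            t = truth.loc[(rec.chrom, rec.pos)]
            expected = {
                "BACKGROUND": (CLASS_BACKGROUND, "", ""),
                "EMS1": (CLASS_EMS1, t["line"], ""),
                "EMS2_YELLOW": (CLASS_EMS2, t["line"], "yellow"),
                "EMS2_GREEN": (CLASS_EMS2, t["line"], "green"),
            }[t["true_class"]]
            assert (rec.label, rec.line, rec.sector) == expected

    def test_false_positive_rate_inflates_unique_counts(self):
        """More spurious calls -> more sector-unique loci, on average."""
        def unique_total(fpr, seed):
            cfg = SimulationConfig(
                genome_length=100_000, n_genes=0, gene_length=100,
                background_snv_rate=5e-5, ems1_count=10, ems2_count=10,
                green_leak_fraction=0.0, n_causal_genes=0,
                false_positive_rate=fpr, seed=seed,
            )
            sim = run_simulation(cfg)
            venn = sim["partition"].venn
            return venn.loc[venn["label"] == CLASS_EMS2, "count"].sum()

        seeds = range(300, 320)
        base = sum(unique_total(0.0, s) for s in seeds)
        noisy = sum(unique_total(3e-4, s) for s in seeds)
        assert noisy > base
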