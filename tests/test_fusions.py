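"""Filter chain, caller intersection, rescue, and isoform enumeration."""

import numpy as np
import pytest

from capfuse import simulate as sim
from capfuse.fusions import (
    BlacklistEntry,
    FilterAudit,
    FusionCall,
    FusionConfig,
    apply_blacklist,
    build_blacklist,
    call_fusions,
    consensus_frame,
    enumerate_isoforms,
    filter_distance,
    filter_on_panel,
    filter_support,
    intersect_callers,
    read_caller_a,
    read_caller_b,
    rescue_known,
    to_caller_a_frame,
    to_caller_b_frame,
)
from capfuse.intervals import CapturePanel, GenomicInterval


def make_call(caller="A", g5="X", g3="Y", bp5=("chr1", 1000, "+"), bp3=("chr2", 5000, "+"),
              junction=5, spanning=5, sample="S1"):
    return FusionCall(caller, sample, g5, g3, bp5, bp3, junction, spanning)


PANEL = CapturePanel("p", [GenomicInterval("chr1", 0, 2000)], ["PG"])


class TestPanelFilter:
    def test_both_partners_on_panel_kept(self):
        c = make_call(bp5=("chr1", 100, "+"), bp3=("chr1", 1500, "+"))
        assert filter_on_panel([c], PANEL) == [c]

    def test_one_novel_offpanel_partner_kept(self):
        # capture pulls down the chimera: one targeted partner suffices
        c = make_call(bp5=("chr1", 100, "+"), bp3=("chr9", 999999, "+"))
        assert filter_on_panel([c], PANEL) == [c]

    def test_neither_partner_removed(self):
        c = make_call(bp5=("chr9", 100, "+"), bp3=("chr9", 999999, "+"))
        audit = FilterAudit()
        assert filter_on_panel([c], PANEL, audit) == []
        assert audit.removed[0]["step"] == "panel"


class TestBlacklist:
    def test_global_entry_removes_everywhere(self):
        bl = [BlacklistEntry("X", "Y")]
        for caller in ("A", "B"):
            assert apply_blacklist([make_call(caller=caller)], bl, "AML") == []

    def test_caller_scoped_entry_spares_other_caller(self):
        bl = [BlacklistEntry("X", "Y", caller_scope="A")]
        assert apply_blacklist([make_call(caller="A")], bl) == []
        kept = apply_blacklist([make_call(caller="B")], bl)
        assert len(kept) == 1

    def test_empty_blacklist_is_identity(self):
        calls = [make_call(), make_call(g5="P", g3="Q")]
        assert apply_blacklist(calls, []) == calls

    def test_build_blacklist_scoped_to_recurrent_caller(self):
        cohort = []
        for s in range(10):
            cohort.append(make_call(caller="A", g5="ART", g3="FACT", sample=f"S{s}"))
            if s < 1:
                cohort.append(make_call(caller="A", g5="RARE", g3="PAIR", sample=f"S{s}"))
            cohort.append(make_call(caller="B", g5="OK", g3="PAIR", sample=f"S{s}"))
        entries = build_blacklist(cohort, min_sample_fraction=0.9)
        assert BlacklistEntry("ART", "FACT", caller_scope="A") in entries
        assert BlacklistEntry("OK", "PAIR", caller_scope="B") in entries
        assert not any(e.gene5 == "RARE" for e in entries)


class TestSupportAndDistance:
    def test_sum_rule_boundary(self):
        assert filter_support([make_call(junction=1, spanning=1)]) != []
        assert filter_support([make_call(junction=1, spanning=0)]) == []
        calls = [make_call(junction=0, spanning=0)]
        assert filter_support(calls, min_reads=0) == calls

    def test_distance_boundary_inclusive(self):
        near = make_call(bp5=("chr1", 1000, "+"), bp3=("chr1", 6000, "+"))
        exact = make_call(bp5=("chr1", 1000, "+"), bp3=("chr1", 11000, "+"))
        inter = make_call(bp5=("chr1", 1000, "+"), bp3=("chr2", 1500, "+"))
        assert filter_distance([near]) == []
        assert filter_distance([exact]) == [exact]
        assert filter_distance([inter]) == [inter]

    @pytest.mark.parametrize("filt", [
        lambda c: filter_support(c, 2),
        lambda c: filter_distance(c, 10000),
        lambda c: filter_on_panel(c, PANEL),
        lambda c: apply_blacklist(c, [BlacklistEntry("X", "Y")]),
    ])
    def test_filters_idempotent_and_non_mutating(self, filt):
        calls = [
            make_call(g5="X", g3="Y", junction=1, spanning=0),
            make_call(g5="P", g3="Q", bp5=("chr1", 100, "+"), bp3=("chr1", 90000, "+")),
            make_call(g5="U", g3="V", bp5=("chr5", 1, "+"), bp3=("chr5", 500, "+")),
        ]
        once = filt(calls)
        assert filt(once) == once
        assert all(c in calls for c in once)  # removal only, never mutation


class TestIntersection:
    def test_identical_call_matches(self):
        a = make_call("A")
        b = make_call("B")
        cons, ra, rb = intersect_callers([a], [b])
        assert len(cons) == 1 and cons[0].tier == "high-confidence"
        assert ra == [] and rb == []
        assert set(cons[0].evidence) == {"A", "B"}

    def test_small_jitter_within_tolerance(self):
        a = make_call("A", bp5=("chr1", 1000, "+"), bp3=("chr2", 5000, "+"))
        b = make_call("B", bp5=("chr1", 1003, "+"), bp3=("chr2", 4998, "+"))
        cons, _, _ = intersect_callers([a], [b], breakpoint_tolerance=10)
        assert len(cons) == 1
        # representative coordinates come from caller A
        assert cons[0].breakpoint5 == ("chr1", 1000, "+")

    def test_beyond_tolerance_not_matched(self):
        a = make_call("A", bp5=("chr1", 1000, "+"))
        b = make_call("B", bp5=("chr1", 1020, "+"))
        cons, ra, rb = intersect_callers([a], [b], breakpoint_tolerance=10)
        assert cons == [] and ra == [a] and rb == [b]

    def test_single_caller_pair_yields_no_consensus(self):
        cons, ra, _ = intersect_callers([make_call("A")], [])
        assert cons == [] and len(ra) == 1

    def test_orientation_is_preserved(self):
        a = make_call("A", g5="KMT2A", g3="AFF1")
        b = make_call("B", g5="AFF1", g3="KMT2A")
        cons, _, _ = intersect_callers([a], [b])
        assert cons == []  # reciprocal fusions are distinct calls

    def test_membership_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        calls_a, calls_b = [], []
        for i in range(30):
            pos5, pos3 = int(rng.integers(0, 5) * 20), int(rng.integers(0, 5) * 20)
            c = make_call("A", g5=f"G{i % 6}", g3="H", bp5=("chr1", 1000 + pos5, "+"), bp3=("chr2", 5000 + pos3, "+"))
            (calls_a if rng.random() < 0.5 else calls_b).append(c)
        swapped_b = [make_call("B", g5=c.gene5, g3=c.gene3, bp5=c.breakpoint5, bp3=c.breakpoint3) for c in calls_b]
        cons1, _, _ = intersect_callers(calls_a, swapped_b)
        swapped_a = [make_call("B", g5=c.gene5, g3=c.gene3, bp5=c.breakpoint5, bp3=c.breakpoint3) for c in calls_a]
        cons2, _, _ = intersect_callers(calls_b, swapped_a)
        pairs1 = sorted((c.gene5, c.gene3) for c in cons1)
        pairs2 = sorted((c.gene5, c.gene3) for c in cons2)
        assert pairs1 == pairs2


class TestRescue:
    KNOWN = [("BCR", "ABL1", {"CML"}), ("EWSR1", "FLI1", {"*"})]

    def test_known_fusion_in_matching_type_rescued(self):
        c = make_call("A", g5="BCR", g3="ABL1")
        out = rescue_known([c], [], self.KNOWN, "CML")
        assert len(out) == 1 and out[0].tier == "single-caller-known"

    def test_unknown_pair_not_rescued(self):
        assert rescue_known([make_call("A", g5="AA", g3="BB")], [], self.KNOWN, "CML") == []

    def test_wrong_cancer_type_not_rescued(self):
        c = make_call("A", g5="BCR", g3="ABL1")
        assert rescue_known([c], [], self.KNOWN, "sarcoma") == []

    def test_wildcard_type_always_rescued(self):
        c = make_call("B", g5="EWSR1", g3="FLI1")
        assert len(rescue_known([], [c], self.KNOWN, "anything")) == 1


class TestCallFusions:
    def test_noiseless_simulation_recovers_truth(self, genes, panel):
        truth = sim.plant_fusions(genes, 4, seed=3)
        err = sim.CallerErrorModel(fp_per_sample=0, shared_fp_rate=0, dropout=0, breakpoint_jitter_sd=0)
        dfa, dfb = sim.simulate_caller_outputs(truth, err, "S1", 7, genes)
        cons, _ = call_fusions(read_caller_a(dfa), read_caller_b(dfb), panel)
        assert sorted((c.gene5, c.gene3) for c in cons) == sorted((t.gene5, t.gene3) for t in truth)
        assert all(c.tier == "high-confidence" for c in cons)

    def test_shared_fp_is_a_known_failure_mode(self, genes, panel):
        err = sim.CallerErrorModel(fp_per_sample=0, shared_fp_rate=3, dropout=0)
        dfa, dfb = sim.simulate_caller_outputs([], err, "S1", 19, genes)
        cons, _ = call_fusions(read_caller_a(dfa), read_caller_b(dfb), panel)
        # identical artifacts in both callers pass the intersection: this is
        # exactly why the recurrent-artifact blacklist exists
        assert len(cons) > 0

    def test_audit_conserves_call_counts(self, genes, panel):
        truth = sim.plant_fusions(genes, 3, seed=23)
        err = sim.CallerErrorModel(fp_per_sample=8, dropout=0.2)
        dfa, dfb = sim.simulate_caller_outputs(truth, err, "S1", 31, genes)
        calls_a, calls_b = read_caller_a(dfa), read_caller_b(dfb)
        cons, audit = call_fusions(calls_a, calls_b, panel)
        removed = sum(s["removed"] for s in audit.steps)
        survivors = sum(len(c.evidence) for c in cons if c.tier == "high-confidence")
        unmatched = len(calls_a) + len(calls_b) - removed - survivors
        assert removed + survivors + unmatched == len(calls_a) + len(calls_b)
        assert len(audit.removed) == removed


class TestIsoforms:
    def test_identical_junctions_merge(self):
        c = lambda s: {"S" + s: [
            make_and_consense(("chr1", 1000, "+"), ("chr2", 5000, "+"))
        ]}
        cat = enumerate_isoforms({**c("1"), **c("2")}, ("TMPRSS2", "ERG"))
        assert len(cat) == 1 and cat[0]["n_samples"] == 2

    def test_distinct_junctions_split(self):
        by_sample = {
            "S1": [make_and_consense(("chr1", 1000, "+"), ("chr2", 5000, "+"))],
            "S2": [make_and_consense(("chr1", 1200, "+"), ("chr2", 5000, "+"))],
        }
        cat = enumerate_isoforms(by_sample, ("TMPRSS2", "ERG"))
        assert len(cat) == 2

    def test_planted_isoforms_recovered(self):
        rng = np.random.default_rng(13)
        junctions = [(("chr21", 1000 * k, "+"), ("chr21", 900000 + 1000 * k, "+")) for k in range(4)]
        by_sample = {}
        expect_counts = {j: 0 for j in range(4)}
        for s in range(12):
            k = int(rng.integers(0, 4))
            bp5, bp3 = junctions[k]
            jit = lambda bp: (bp[0], bp[1] + int(rng.integers(-3, 4)), bp[2])
            by_sample[f"S{s:02d}"] = [make_and_consense(jit(bp5), jit(bp3))]
            expect_counts[k] += 1
        cat = enumerate_isoforms(by_sample, ("TMPRSS2", "ERG"))
        assert len(cat) == len([v for v in expect_counts.values() if v])
        assert sorted(c["n_samples"] for c in cat) == sorted(v for v in expect_counts.values() if v)


def make_and_consense(bp5, bp3, g5="TMPRSS2", g3="ERG"):
    from capfuse.fusions import ConsensusFusion

    return ConsensusFusion(g5, g3, bp5, bp3, "high-confidence")


class TestDialects:
    def test_caller_a_roundtrip(self):
        rows = [{"gene5": "BCR", "gene3": "ABL1", "bp5": ("chr22", 100, "+"),
                 "bp3": ("chr9", 200, "-"), "junction_reads": 7, "spanning_reads": 3}]
        calls = read_caller_a(to_caller_a_frame(rows))
        c = calls[0]
        assert (c.gene5, c.gene3) == ("BCR", "ABL1")
        assert c.breakpoint5 == ("chr22", 100, "+")
        assert (c.junction_reads, c.spanning_reads) == (7, 3)

    def test_caller_b_roundtrip_column_semantics(self):
        rows = [{"gene5": "BCR", "gene3": "ABL1", "bp5": ("chr22", 100, "+"),
                 "bp3": ("chr9", 200, "-"), "junction_reads": 7, "spanning_reads": 3}]
        df = to_caller_b_frame(rows)
        assert df.loc[0, "Spanning_unique_reads"] == 7  # junction reads
        assert df.loc[0, "Spanning_pairs"] == 3
        c = read_caller_b(df)[0]
        assert (c.junction_reads, c.spanning_reads) == (7, 3)

    def test_breakpoints_are_one_based_in_tables(self):
        rows = [{"gene5": "A", "gene3": "B", "bp5": ("chr1", 0, "+"),
                 "bp3": ("chr2", 9, "+"), "junction_reads": 2, "spanning_reads": 0}]
        df = to_caller_a_frame(rows)
        assert df.loc[0, "LeftBreakpoint"] == "chr1:1:+"

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            read_caller_a(pd.DataFrame({"FusionName": ["A--B"]}))

    def test_consensus_frame_columns(self):
        cons = [make_and_consense(("chr1", 10, "+"), ("chr2", 20, "+"))]
        df = consensus_frame(cons)
        assert list(df["tier"]) == ["high-confidence"]
        assert df.loc[0, "breakpoint5"] == "chr1:11:+"
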