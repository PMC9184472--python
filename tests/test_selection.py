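import itertools
import math

import numpy as np
import pandas as pd
import pytest

from exonqpcr import foldchange, selection, synth
from exonqpcr.model import Config, FULL, HIGH_DOSE_ONLY, NONE, UNDETERMINED

CFG = Config()


class TestDetectability:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ([math.nan, math.nan, math.nan], False),
            ([math.nan, 36.5, math.nan], True),
            ([28.0, 28.2], True),
        ],
    )
    def test_all_censored_means_not_detectable(self, cts, expected):
        rec = pd.DataFrame(
            {"assay_id": "A", "ct": cts, "censored": [math.isnan(c) for c in cts]}
        )
        assert selection.assess_detectability(rec)["A"] == expected


class TestBaselineCriterion:
    @pytest.mark.parametrize(
        "baseline, direction, expected",
        [
            (28.0, "up", True),    # typical detectable baseline
            (34.0, "up", False),   # weak-expression assay
            (30.0, "down", False), # strict boundary
            (29.9, "down", True),
            (33.0, "up", False),   # strict boundary
            (math.nan, "up", False),
        ],
    )
    def test_thresholds(self, baseline, direction, expected):
        assert selection.baseline_criterion(baseline, direction, CFG) is expected


class TestDoseDependency:
    @pytest.mark.parametrize(
        "fc, direction, verdict",
        [
            ({0: 1, 0.5: 10, 4: 12}, "up", FULL),      # 12 is the minimum pass
            ({0: 1, 0.5: 10, 4: 11.9}, "up", HIGH_DOSE_ONLY),
            ({0: 1, 0.5: 1.5, 4: 2.4}, "up", NONE),
            ({0: 1, 0.5: 1.0, 4: 3.0}, "up", HIGH_DOSE_ONLY),
            ({0: 1, 0.5: 0.6, 4: 0.2}, "down", HIGH_DOSE_ONLY),
            ({0: 1, 0.5: 0.5, 4: 0.25}, "down", FULL),
            ({0: 1, 0.5: 0.8, 4: 0.6}, "down", NONE),
            ({0: 1, 0.5: 10}, "up", UNDETERMINED),
        ],
    )
    def test_verdicts(self, fc, direction, verdict):
        assert selection.dose_dependency_criterion(fc, direction, CFG) == verdict


class TestPersistency:
    @pytest.mark.parametrize(
        "fc24, fc48, expected",
        [(10.5, 9.5, True), (10.5, 11.5, True), (10.5, 11.6, False),
         (3.3, 3.3, True), (math.nan, 3.0, False)],
    )
    def test_margin_inclusive(self, fc24, fc48, expected):
        assert selection.persistency_criterion(fc24, fc48, CFG) is expected


def _donor_fc(cells):
    """cells: {(dose, time): {donor: fc}} -> frame for one assay."""
    rows = [
        {"donor_id": d, "dose_gy": dose, "time_h": t, "fc": fc}
        for (dose, t), donors in cells.items()
        for d, fc in donors.items()
    ]
    return pd.DataFrame(rows)


class TestVariabilityScore:
    def test_zero_for_identical_donors(self):
        cells = {
            (x, t): {"d1": 2.0, "d2": 2.0, "d3": 2.0}
            for x, t in itertools.product([0.0, 0.5, 4.0], [24.0, 48.0])
        }
        assert selection.variability_score(_donor_fc(cells), CFG) == 0.0

    def test_single_spread_cell(self):
        """Sample SD of {1, 2, 3} donor FCs in one cell is exactly 1."""
        cells = {
            (x, t): {"d1": 1.0, "d2": 1.0, "d3": 1.0}
            for x, t in itertools.product([0.0, 0.5, 4.0], [24.0, 48.0])
        }
        cells[(4.0, 24.0)] = {"d1": 1.0, "d2": 2.0, "d3": 3.0}
        assert selection.variability_score(_donor_fc(cells), CFG) == pytest.approx(1.0)

    def test_homogeneity(self):
        cells = {
            (x, t): {"d1": 1.0, "d2": 2.0, "d3": 4.0}
            for x, t in itertools.product([0.0, 0.5, 4.0], [24.0, 48.0])
        }
        df = _donor_fc(cells)
        base = selection.variability_score(df, CFG)
        doubled = df.assign(fc=df.fc * 2)
        assert selection.variability_score(doubled, CFG) == pytest.approx(2 * base)

    def test_sham_toggle(self):
        cells = {
            (x, t): {"d1": 1.0, "d2": 2.0, "d3": 3.0}
            for x, t in itertools.product([0.0, 4.0], [24.0])
        }
        import dataclasses
        no_sham = dataclasses.replace(CFG, variability_include_sham=False,
                                      doses=(0.0, 4.0))
        df = _donor_fc(cells)
        assert selection.variability_score(df, no_sham) == pytest.approx(1.0)


class TestRankAndTertile:
    def test_fourteen_assays_rank_one_to_fourteen(self):
        scores = {f"A{i:02d}": float(i) for i in range(14)}
        out = selection.rank_and_tertile(scores)
        assert sorted(r for r, _ in out.values()) == list(range(1, 15))

    def test_five_assays_split_2_2_1(self):
        scores = {f"A{i}": float(i) for i in range(5)}
        out = selection.rank_and_tertile(scores)
        tertiles = [out[f"A{i}"][1] for i in range(5)]
        assert tertiles == ["upper", "upper", "middle", "middle", "lower"]

    def test_ties_break_by_assay_id(self):
        out = selection.rank_and_tertile({"B": 1.0, "A": 1.0, "C": 0.5})
        assert out["C"][0] == 1 and out["A"][0] == 2 and out["B"][0] == 3

    def test_empty_input(self):
        assert selection.rank_and_tertile({}) == {}

    def test_rank_oracle_brute_force(self):
        """Ranks agree with a brute-force sort of independently computed
        summed SDs for a small (5-assay) panel."""
        rng = np.random.default_rng(5)
        donor_fc = {}
        for a in ["W1", "W2", "W3", "W4", "W5"]:
            donor_fc[a] = {
                (x, t): dict(zip("abc", rng.lognormal(0, 0.5, 3)))
                for x, t in itertools.product([0.0, 0.5, 4.0], [24.0, 48.0])
            }
        scores = {
            a: selection.variability_score(_donor_fc(cells), CFG)
            for a, cells in donor_fc.items()
        }
        # independent recomputation: explicit loops, textbook sample SD
        brute = {}
        for a, cells in donor_fc.items():
            total = 0.0
            for donors in cells.values():
                vals = list(donors.values())
                m = sum(vals) / len(vals)
                total += math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            brute[a] = total
        expected_order = sorted(brute, key=lambda a: (brute[a], a))
        got = selection.rank_and_tertile(scores)
        assert [a for a, _ in sorted(got.items(), key=lambda kv: kv[1][0])] == \
            expected_order
        for a in brute:
            assert scores[a] == pytest.approx(brute[a])

    def test_added_spread_never_improves_rank(self):
        """Inflating one assay's donor spread cannot move it to a better
        (lower) rank while the others stay unchanged."""
        rng = np.random.default_rng(9)
        base = {
            a: {
                (x, t): dict(zip("abc", rng.lognormal(0, 0.3, 3)))
                for x, t in itertools.product([0.0, 0.5, 4.0], [24.0, 48.0])
            }
            for a in "ABCDE"
        }
        scores = {
            a: selection.variability_score(_donor_fc(c), CFG) for a, c in base.items()
        }
        before = selection.rank_and_tertile(scores)["C"][0]
        inflated = {
            cell: {d: 1.0 + (fc - 1.0) * 3.0 for d, fc in donors.items()}
            for cell, donors in base["C"].items()
        }
        scores["C"] = selection.variability_score(_donor_fc(inflated), CFG)
        after = selection.rank_and_tertile(scores)["C"][0]
        assert after >= before


class TestDirectionInference:
    def _fc(self, gene, fcs):
        return pd.DataFrame(
            {"gene": gene, "dose_gy": 4.0, "fc": fcs, "assay_id": "A",
             "donor_id": [f"d{i}" for i in range(len(fcs))], "time_h": 24.0}
        )

    def test_median_above_one_is_up(self):
        assert selection.infer_direction(self._fc("FDXR", [18, 20, 22]), "FDXR", CFG) == "up"

    def test_median_below_one_is_down(self):
        assert selection.infer_direction(self._fc("POU2AF1", [0.2, 0.3, 0.4]),
                                         "POU2AF1", CFG) == "down"

    def test_exact_tie_classifies_down(self):
        assert selection.infer_direction(self._fc("G", [1.0, 1.0, 1.0]), "G", CFG) == "down"

    def test_override_wins(self):
        import dataclasses
        cfg = dataclasses.replace(CFG, direction_override={"G": "up"})
        assert selection.infer_direction(self._fc("G", [0.1, 0.1, 0.1]), "G", cfg) == "up"


class TestSelect:
    def _evaluations(self, rows):
        cols = ["gene", "assay_id", "detectable", "baseline_pass",
                "dose_dependency", "persistency_pass", "selected", "rank"]
        df = pd.DataFrame(rows, columns=cols[:-2] + ["rank"])
        df["selected"] = (
            df.detectable & df.baseline_pass
            & df.dose_dependency.isin([FULL, HIGH_DOSE_ONLY]) & df.persistency_pass
        )
        return df

    def test_fdxr_reference_rows_all_selected(self):
        """The four FDXR rows with baselines 28–29, full dose dependency and
        persistent fold changes all pass; the lowest-rank one leads."""
        rows = [
            ("FDXR", "Hs01031621_g1", True, True, FULL, True, 1),
            ("FDXR", "AR7DTG3", True, True, FULL, True, 3),
            ("FDXR", "Hs00244586_m1", True, True, FULL, True, 2),
            ("FDXR", "Hs01031617_m1", True, True, FULL, True, 4),
        ]
        out = selection.select_assays(self._evaluations(rows))
        assert len(out["FDXR"]) == 4 and out["FDXR"][0] == "Hs01031621_g1"

    def test_single_failed_criterion_excludes(self):
        rows = [("FDXR", "A", True, False, FULL, True, 1)]
        assert selection.select_assays(self._evaluations(rows)) == {"FDXR": []}

    def test_empty_gene(self):
        ev = self._evaluations([("FDXR", "A", True, True, FULL, True, 1)])
        assert selection.select_assays(ev[ev.gene == "WNT3"]) == {}


def test_evaluation_is_deterministic(scenario_dataset, tmp_path):
    """Identical datasets give byte-identical evaluation tables."""
    from exonqpcr import io

    dataset, _ = scenario_dataset
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    io.write_evaluation_table(selection.evaluate_assays(dataset), p1)
    io.write_evaluation_table(selection.evaluate_assays(dataset), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_undetermined_assays_are_reported_not_dropped():
    """An assay missing a whole dose level appears in the output with an
    undetermined dose-dependency verdict and is not selectable."""
    from conftest import grid_rows, make_tiny_dataset

    manifest = [("A1", "FDXR", 1, "m1", False), ("A2", "FDXR", 2, "m1", False)]
    genes = {"A1": "FDXR", "A2": "FDXR"}
    baselines = {"A1": 28.0, "A2": 28.0}
    profile = {(0.5, 24.0): 10, (0.5, 48.0): 10, (4.0, 24.0): 30, (4.0, 48.0): 30}
    rows = grid_rows({"A1": profile, "A2": profile}, baselines, genes)
    rows = [r for r in rows if not (r[4] == "A2" and r[1] == 4.0)]
    ds = make_tiny_dataset(rows, manifest)
    ev = selection.evaluate_assays(ds).set_index("assay_id")
    assert ev.loc["A2", "dose_dependency"] == UNDETERMINED
    assert not ev.loc["A2", "selected"]
    assert ev.loc["A1", "dose_dependency"] == FULL and ev.loc["A1", "selected"]
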