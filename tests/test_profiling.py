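"""Panel summaries, chemo-marker frequencies and Kjeldahl protein."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedqnmr as sq
from seedqnmr.profiling import PanelMatrix
from seedqnmr.quantify import ConcentrationProfile
from seedqnmr.signature import EXPECTED_CLASS_TALLIES


def profile_with(library, names_to_conc):
    conc = {e.name: names_to_conc.get(e.name, 0.0) for e in library.entries}
    present = {k: v > 0 for k, v in conc.items()}
    return ConcentrationProfile(line_id="L", conc_mg_per_g=conc, present=present)


class TestMetaboliteCounts:
    def test_full_roster_counts(self, library):
        prof = profile_with(library, {e.name: 1.0 for e in library.entries})
        counts = sq.metabolite_counts(prof, library)
        assert counts["total"] == 45
        for cls, n in EXPECTED_CLASS_TALLIES.items():
            assert counts[cls] == n

    def test_empty_profile_counts_zero(self, library):
        counts = sq.metabolite_counts(profile_with(library, {}), library)
        assert counts["total"] == 0
        assert all(v == 0 for k, v in counts.items())

    def test_single_class_partition(self, library):
        aminos = {
            e.name: 1.0 for e in library.entries if e.metabolite_class == "amino_acid"
        }
        counts = sq.metabolite_counts(profile_with(library, aminos), library)
        assert counts["total"] == counts["amino_acid"] == 17
        assert counts["sugar"] == counts["vitamin"] == 0

    def test_unknown_metabolite_rejected(self, library):
        prof = ConcentrationProfile(
            line_id="L", conc_mg_per_g={"nope": 1.0}, present={"nope": True}
        )
        with pytest.raises(KeyError):
            sq.metabolite_counts(prof, library)


class TestClassTotals:
    def test_single_metabolite_total(self, library):
        totals = sq.class_totals(profile_with(library, {"methionine": 2.0}), library)
        assert totals["amino_acid"] == pytest.approx(2.0)
        assert totals["total"] == pytest.approx(2.0)

    def test_linearity_under_doubling(self, library):
        conc = {"methionine": 1.5, "rutin": 2.5, "thiamine": 0.5}
        t1 = sq.class_totals(profile_with(library, conc), library)
        t2 = sq.class_totals(
            profile_with(library, {k: 2 * v for k, v in conc.items()}), library
        )
        for k in t1:
            assert t2[k] == pytest.approx(2 * t1[k])

    def test_round_trip_class_totals_match_truth(self, library, noiseless_params):
        spectra, truths = sq.simulate_panel(
            1, seed=31, params=noiseless_params, library=library
        )
        prof = sq.quantify_spectrum(spectra[0], library=library)
        totals = sq.class_totals(prof, library)
        true_totals = {}
        for e in library.entries:
            if e.name in truths[0].masses_mg:
                c = truths[0].masses_mg[e.name] / 0.5
                true_totals[e.metabolite_class] = (
                    true_totals.get(e.metabolite_class, 0.0) + c
                )
        for cls, t in true_totals.items():
            assert totals[cls] == pytest.approx(t, rel=0.05)


class TestChemomarkers:
    def make_panel(self, library, presence_rows):
        names = library.names()
        conc = pd.DataFrame(
            [[1.0 if n in row else 0.0 for n in names] for row in presence_rows],
            columns=names,
            index=[f"L{i}" for i in range(len(presence_rows))],
        )
        conc.index.name = "line_id"
        return PanelMatrix(conc=conc)

    def test_frequency_arithmetic_and_threshold(self, library):
        rows = [{"methionine"}] * 95 + [set()]
        panel = self.make_panel(library, rows)
        rep = sq.chemomarker_report(panel, min_fraction=0.95)
        met = rep[rep.metabolite == "methionine"].iloc[0]
        assert met.frequency == pytest.approx(95 / 96, abs=1e-9)
        assert bool(met.near_universal)

    def test_absent_metabolite_not_listed(self, library):
        panel = self.make_panel(library, [{"methionine"}] * 4)
        rep = sq.chemomarker_report(panel)
        rutin = rep[rep.metabolite == "rutin"].iloc[0]
        assert rutin.frequency == 0.0 and not bool(rutin.near_universal)

    def test_zero_threshold_lists_everything(self, library):
        panel = self.make_panel(library, [{"methionine"}, set()])
        rep = sq.chemomarker_report(panel, min_fraction=0.0)
        assert rep.near_universal.all()

    def test_line_order_invariance(self, library):
        rows = [{"methionine"}, {"rutin"}, {"methionine", "rutin"}, set()]
        a = sq.chemomarker_report(self.make_panel(library, rows))
        b = sq.chemomarker_report(self.make_panel(library, rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_panel_rejected(self, library):
        panel = self.make_panel(library, [set()])
        empty = PanelMatrix(conc=panel.conc.iloc[:0])
        with pytest.raises(ValueError):
            sq.chemomarker_report(empty)


class TestKjeldahl:
    def test_equal_titres_give_zero(self):
        p = sq.KjeldahlParams(V_sample=1.0, V_blank=1.0)
        assert sq.kjeldahl_protein(p) == 0.0

    def test_hand_worked_example(self):
        # %N = (5.0-0.2)*0.1*1.4007/0.25 = 2.6893; protein = 16.8084
        p = sq.KjeldahlParams(
            V_sample=5.0, V_blank=0.2, normality=0.1, sample_mass_g=0.25
        )
        assert sq.kjeldahl_protein(p) == pytest.approx(16.81, abs=0.005)

    def test_linearity_in_net_titre(self):
        p1 = sq.KjeldahlParams(V_sample=2.2, V_blank=0.2)
        p2 = sq.KjeldahlParams(V_sample=4.2, V_blank=0.2)
        assert sq.kjeldahl_protein(p2) == pytest.approx(2 * sq.kjeldahl_protein(p1))

    @settings(max_examples=100, deadline=None)
    @given(
        v=st.floats(min_value=0.5, max_value=10.0),
        dv=st.floats(min_value=0.01, max_value=5.0),
        m=st.floats(min_value=0.1, max_value=0.5),
        dm=st.floats(min_value=0.01, max_value=0.3),
    )
    def test_monotonicity(self, v, dv, m, dm):
        base = sq.kjeldahl_protein(sq.KjeldahlParams(V_sample=v, sample_mass_g=m))
        more_titre = sq.kjeldahl_protein(
            sq.KjeldahlParams(V_sample=v + dv, sample_mass_g=m)
        )
        more_mass = sq.kjeldahl_protein(
            sq.KjeldahlParams(V_sample=v, sample_mass_g=m + dm)
        )
        assert more_titre > base
        assert more_mass < base

    def test_blank_exceeding_sample_rejected(self):
        with pytest.raises(ValueError):
            sq.KjeldahlParams(V_sample=0.1, V_blank=0.5)


class TestPanelSummary:
    def test_summary_columns_and_counts(self, library, noiseless_params):
        spectra, truths = sq.simulate_panel(
            2, seed=41, params=noiseless_params, library=library
        )
        profiles = [sq.quantify_spectrum(s, library=library) for s in spectra]
        panel = PanelMatrix.from_profiles(profiles, library)
        summ = sq.panel_summary(panel, library)
        assert len(summ) == 2
        assert (summ.n_total <= 45).all()
        row = summ.iloc[0]
        class_cols = [c for c in summ.columns if c.startswith("n_") and c != "n_total"]
        assert sum(row[c] for c in class_cols) == row.n_total

    def test_matrix_csv_round_trip(self, library, noiseless_params, tmp_path):
        spectra, _ = sq.simulate_panel(
            2, seed=42, params=noiseless_params, library=library
        )
        profiles = [sq.quantify_spectrum(s, library=library) for s in spectra]
        panel = PanelMatrix.from_profiles(
            profiles, library, protein_pct={p.line_id: 20.0 for p in profiles}
        )
        path = tmp_path / "panel.csv"
        panel.to_csv(path)
        back = PanelMatrix.from_csv(path)
        assert back.metabolites == panel.metabolites
        assert np.allclose(back.conc.to_numpy(), panel.conc.to_numpy(), rtol=1e-5)
        assert back.protein_pct is not None
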