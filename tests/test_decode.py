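import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from duospot.decode import (
    DecodedSignal,
    apply_artifact_masks,
    apply_masks,
    assign_to_cells,
    autofluorescence_objects,
    colocalize_code,
    decode_signals,
    signals_to_frame,
)
from duospot.segmentation import CellLabelMap
from duospot.simgen import MARKERS


def spot_table(rows):
    """rows: (channel, x, y) triples."""
    return pd.DataFrame(
        {
            "channel": [r[0] for r in rows],
            "x": [r[1] for r in rows],
            "y": [r[2] for r in rows],
            "peak_intensity": 1000.0,
            "area": 5,
        }
    )


class TestColocalizeCode:
    def test_close_pair_found(self):
        spots = spot_table([("Cy3", 10, 10), ("TexasRed", 11, 10)])
        assert len(colocalize_code(spots, ("Cy3", "TexasRed"), 2.5)) == 1

    def test_distant_pair_rejected(self):
        spots = spot_table([("Cy3", 10, 10), ("TexasRed", 15, 10)])
        assert colocalize_code(spots, ("Cy3", "TexasRed"), 2.5) == []

    def test_nearer_partner_wins(self):
        spots = spot_table([("Cy3", 10, 10), ("TexasRed", 12, 10), ("TexasRed", 9, 10)])
        pairs = colocalize_code(spots, ("Cy3", "TexasRed"), 2.5)
        assert len(pairs) == 1
        ia, ib, d = pairs[0]
        assert spots.at[ib, "x"] == 9  # 1 px beats 2 px

    def test_one_to_one(self):
        spots = spot_table(
            [("Cy3", 10, 10), ("Cy3", 12, 10), ("TexasRed", 11, 10)]
        )
        pairs = colocalize_code(spots, ("Cy3", "TexasRed"), 2.5)
        assert len(pairs) == 1

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            colocalize_code(spot_table([]), ("Cy3", "Cy5"), 0)

    def test_greedy_agrees_with_optimal_matching(self):
        # brute-force minimum-weight matching oracle on random small instances
        rng = np.random.default_rng(0)
        agree = 0
        n_trials = 200
        for _ in range(n_trials):
            na, nb = rng.integers(1, 6, 2)
            rows = [("A", rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(na)]
            rows += [("B", rng.uniform(0, 50), rng.uniform(0, 50)) for _ in range(nb)]
            spots = spot_table(rows)
            greedy = {frozenset(p[:2]) for p in colocalize_code(spots, ("A", "B"), 2.5)}

            a = spots[spots.channel == "A"]
            b = spots[spots.channel == "B"]
            cost = np.hypot(
                a.y.to_numpy()[:, None] - b.y.to_numpy()[None, :],
                a.x.to_numpy()[:, None] - b.x.to_numpy()[None, :],
            )
            big = 1e6
            padded = np.where(cost <= 2.5, cost, big)
            ri, ci = linear_sum_assignment(padded)
            optimal = {
                frozenset((a.index[i], b.index[j]))
                for i, j in zip(ri, ci)
                if padded[i, j] < big
            }
            if greedy == optimal:
                agree += 1
        assert agree / n_trials >= 0.99


class TestDecodeSignals:
    def test_hem_pair_accepted(self, panel):
        spots = spot_table([("Cy3", 20, 20), ("TexasRed", 20, 21)])
        signals = decode_signals(spots, panel, 2.5)
        accepted = [s for s in signals if s.accepted]
        assert len(accepted) == 1
        assert accepted[0].marker == "hem"

    def test_lone_spot_rejected_single_channel(self, panel):
        signals = decode_signals(spot_table([("Cy5", 20, 20)]), panel, 2.5)
        assert [s.status for s in signals] == ["rejected_single_channel"]

    def test_five_channel_group_unspecific(self, panel):
        rows = [(ch, 20, 20) for ch in ("Atto425", "Atto488", "Cy3", "Cy5", "AF750")]
        signals = decode_signals(spot_table(rows), panel, 2.5)
        assert signals
        assert all(s.status == "unspecific_multichannel" for s in signals)

    def test_off_code_pair_rejected(self, panel):
        # TexasRed pairs only with Cy3 in the default panel
        spots = spot_table([("TexasRed", 20, 20), ("Cy5", 20, 21)])
        signals = decode_signals(spots, panel, 2.5)
        assert [s.status for s in signals] == ["rejected_off_code"]

    def test_three_channel_group_decodes_constituent_codes(self, panel):
        # {Atto488, Cy3, Cy5} = VIM + AR-FL + PSMA sharing a location
        rows = [("Atto488", 20, 20), ("Cy3", 20, 21), ("Cy5", 21, 20)]
        signals = decode_signals(spot_table(rows), panel, 2.5)
        markers = {s.marker for s in signals if s.accepted}
        assert markers == {"VIM", "AR-FL", "PSMA"}

    def test_empty_input(self, panel):
        assert decode_signals(spot_table([]), panel, 2.5) == []

    def test_partition_over_statuses(self, panel):
        rng = np.random.default_rng(5)
        channels = list(panel.signal_channels)
        rows = [
            (channels[rng.integers(len(channels))], rng.uniform(0, 100), rng.uniform(0, 100))
            for _ in range(120)
        ]
        spots = spot_table(rows)
        signals = decode_signals(spots, panel, 2.5)
        # every candidate carries exactly one status
        assert all(isinstance(s.status, str) for s in signals)
        # every spot appears in at least one signal record
        covered = set()
        for s in signals:
            covered.update(s.spot_ids)
        assert covered == set(range(len(spots)))


class TestApplyMasks:
    def _accepted(self, marker, x, y):
        return DecodedSignal(marker=marker, x=x, y=y, spot_ids=(0, 1))

    def test_arfl_masked_by_vim(self):
        signals = [self._accepted("AR-FL", 10, 10), self._accepted("VIM", 10.5, 10)]
        out = apply_masks(signals, 2.5)
        statuses = {s.marker: s.status for s in out}
        assert statuses["AR-FL"] == "masked_by:VIM"
        assert statuses["VIM"] == "accepted"

    def test_epcam_masked_by_psa(self):
        signals = [self._accepted("EPCAM", 10, 10), self._accepted("PSA", 11, 10)]
        out = apply_masks(signals, 2.5)
        assert {s.status for s in out} == {"masked_by:PSA", "accepted"}

    def test_krt_and_vim_both_survive(self):
        signals = [self._accepted("KRT", 10, 10), self._accepted("VIM", 10, 10)]
        out = apply_masks(signals, 2.5)
        assert all(s.accepted for s in out)

    def test_masked_arfl_still_masks_level2(self):
        signals = [
            self._accepted("AR-FL", 10, 10),
            self._accepted("VIM", 10.5, 10),
            self._accepted("EPCAM", 50, 50),
            self._accepted("PSMA", 10, 10.5),
        ]
        out = apply_masks(signals, 2.5)
        statuses = {s.marker: s.status for s in out}
        assert statuses["AR-FL"] == "masked_by:VIM"
        assert statuses["PSMA"].startswith("masked_by:")
        assert statuses["EPCAM"] == "accepted"  # far away

    def test_distant_signals_untouched(self):
        signals = [self._accepted("AR-FL", 10, 10), self._accepted("VIM", 50, 50)]
        assert all(s.accepted for s in apply_masks(signals, 2.5))

    def _random_signals(self, seed, n=60):
        rng = np.random.default_rng(seed)
        markers = list(MARKERS)
        return [
            self._accepted(
                markers[rng.integers(len(markers))], rng.uniform(0, 40), rng.uniform(0, 40)
            )
            for _ in range(n)
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_never_increases_accepted_count(self, seed):
        signals = self._random_signals(seed)
        out = apply_masks(signals, 2.5)
        assert sum(s.accepted for s in out) <= sum(s.accepted for s in signals)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        once = apply_masks(self._random_signals(seed), 2.5)
        twice = apply_masks(once, 2.5)
        assert [s.status for s in twice] == [s.status for s in once]


class TestAutofluorescence:
    def _blob(self, shape, center, amp):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return amp * np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * 3.0**2))

    def test_dual_channel_object_masked(self):
        a = self._blob((64, 64), (30, 30), 2000)
        b = self._blob((64, 64), (30, 30), 1500)
        mask = autofluorescence_objects(a, b, window=64, lower_bound=200)
        assert mask[30, 30]

    def test_single_channel_object_not_masked(self):
        a = self._blob((64, 64), (30, 30), 2000)
        b = np.zeros((64, 64))
        mask = autofluorescence_objects(a, b, window=64, lower_bound=200)
        assert not mask[30, 30]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            autofluorescence_objects(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_border_void_masks_signal(self):
        validity = np.ones((64, 64), bool)
        validity[:, :10] = False
        signals = [
            DecodedSignal("hem", 5, 30, (0, 1)),
            DecodedSignal("hem", 40, 30, (2, 3)),
        ]
        out = apply_artifact_masks(signals, None, validity)
        assert out[0].status == "masked_border"
        assert out[1].status == "accepted"

    def test_autofluor_mask_applies(self):
        mask = np.zeros((64, 64), bool)
        mask[28:33, 28:33] = True
        signals = [DecodedSignal("KRT", 30, 30, (0, 1))]
        out = apply_artifact_masks(signals, mask, None)
        assert out[0].status == "masked_autofluor"


class TestAssignToCells:
    def _cells(self):
        labels = np.zeros((32, 32), np.int32)
        labels[5:15, 5:15] = 3
        labels[20:30, 20:30] = 7
        return CellLabelMap(labels=labels, expansion_px={3: 12, 7: 12})

    def test_signal_inside_cell_counted(self):
        signals = [DecodedSignal("hem", 10, 10, (0, 1))]
        assigned, table = assign_to_cells(signals, self._cells(), MARKERS)
        assert assigned[0].cell_id == 3
        assert table.set_index("cell_id").loc[3, "hem"] == 1

    def test_background_signal_unassigned(self):
        signals = [DecodedSignal("hem", 0, 0, (0, 1))]
        assigned, table = assign_to_cells(signals, self._cells(), MARKERS)
        assert assigned[0].cell_id is None
        assert table["total"].sum() == 0

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(3)
        markers = list(MARKERS)
        signals = [
            DecodedSignal(
                markers[rng.integers(len(markers))],
                float(rng.uniform(0, 31)),
                float(rng.uniform(0, 31)),
                (0, 1),
            )
            for _ in range(50)
        ]
        assigned, table = assign_to_cells(signals, self._cells(), MARKERS)
        n_assigned = sum(1 for s in assigned if s.cell_id is not None)
        assert table[list(MARKERS)].to_numpy().sum() == n_assigned
        assert (table[list(MARKERS)].sum(axis=1) == table["total"]).all()

    def test_masked_signals_not_counted(self):
        signals = [
            DecodedSignal("hem", 10, 10, (0, 1), status="masked_by:VIM"),
            DecodedSignal("hem", 11, 10, (2, 3), status="rejected_single_channel"),
        ]
        _, table = assign_to_cells(signals, self._cells(), MARKERS)
        assert table["total"].sum() == 0


def test_signals_frame_columns():
    frame = signals_to_frame([DecodedSignal("hem", 1.0, 2.0, (0, 1), cell_id=4)])
    assert list(frame.columns) == ["marker", "x", "y", "status", "cell_id", "n_spots"]
    assert frame.loc[0, "cell_id"] == 4
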