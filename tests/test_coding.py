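"""Threshold coding, code assembly, counting, and library matching."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipcode import (
    BinaryCode,
    ChannelDifference,
    CodeLibrary,
    CodingConfig,
    LibraryEntry,
    WellColorValue,
    assemble_code,
    codes_by_assay,
    compute_differences,
    count_color_changes,
    digit_from_difference,
    hamming,
    match_code,
)
from chipcode.coding import differences_to_frame
from chipcode.errors import (
    AssemblyError,
    CompatibilityError,
    EmptyLibraryError,
    PairingError,
)
from chipcode.plate import WellAddress


def wcv(addr, r, g, b, n=317):
    return WellColorValue(WellAddress.parse(addr), r, g, b, n)


def diff(delta, ch="G"):
    return ChannelDifference("P01", "DC1", 1, ch, delta)


class TestDifferences:
    def test_identical_wells_give_zero_deltas(self, tiny_layout):
        totals = [wcv("A1", 5000, 5000, 5000), wcv("A2", 5000, 5000, 5000)]
        assert [d.delta for d in compute_differences(totals, tiny_layout)] == [0, 0, 0]

    def test_sign_convention_control_minus_analyte(self, tiny_layout):
        totals = [wcv("A1", 1000, 60000, 0), wcv("A2", 2500, 57000, 0)]
        diffs = {d.channel: d.delta for d in compute_differences(totals, tiny_layout)}
        assert diffs["G"] == +3000
        assert diffs["R"] == -1500

    def test_missing_partner_is_pairing_error(self, tiny_layout):
        with pytest.raises(PairingError):
            compute_differences([wcv("A1", 0, 0, 0)], tiny_layout)

    def test_differences_frame_columns(self, tiny_layout):
        totals = [wcv("A1", 1, 2, 3), wcv("A2", 0, 0, 0)]
        df = differences_to_frame(compute_differences(totals, tiny_layout))
        assert list(df.columns) == ["pair", "sensor", "condition", "channel", "delta"]

    def test_totals_order_does_not_matter(self, layout96):
        import numpy as np

        rng = np.random.default_rng(3)
        totals = [
            WellColorValue(addr, int(rng.integers(0, 80000)), int(rng.integers(0, 80000)),
                           int(rng.integers(0, 80000)), 317)
            for addr in layout96.well_map
        ]
        a = compute_differences(totals, layout96)
        b = compute_differences(list(reversed(totals)), layout96)
        assert a == b


class TestDigits:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0, 0), (999, 0), (1000, 1), (-1500, 1), (-999, 0), (-1000, 1), (50000, 1)],
    )
    def test_inclusive_absolute_threshold(self, delta, expected):
        assert digit_from_difference(diff(delta), CodingConfig(1000)) == expected

    def test_default_threshold_is_1000(self):
        assert CodingConfig().threshold == 1000

    @given(st.integers(-80000, 80000), st.integers(0, 5000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_magnitude(self, delta, bump):
        cfg = CodingConfig(1000)
        grown = delta + bump if delta >= 0 else delta - bump
        assert digit_from_difference(diff(delta), cfg) <= digit_from_difference(diff(grown), cfg)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            CodingConfig(0)


class TestAssembly:
    def test_all_zero_code(self, layout96):
        digits = {s: 0 for s in layout96.digit_slots()}
        code = assemble_code(digits, layout96)
        assert code.digits == "0" * 48
        assert count_color_changes(code) == 0

    def test_single_one_lands_at_canonical_position(self, layout96):
        digits = {s: 0 for s in layout96.digit_slots()}
        digits[("DC1", 1, "G")] = 1
        code = assemble_code(digits, layout96)
        # canonical order: DC1-cond1-(R,G,B) occupies positions 0..2
        assert code.digits.index("1") == 1
        assert count_color_changes(code) == 1

    def test_code_length_48_for_default_layout(self, layout96):
        digits = {s: 1 for s in layout96.digit_slots()}
        assert len(assemble_code(digits, layout96)) == 48

    def test_missing_slot_raises(self, layout96):
        digits = {s: 0 for s in layout96.digit_slots()[:-1]}
        with pytest.raises(AssemblyError):
            assemble_code(digits, layout96)

    def test_unknown_slot_raises(self, tiny_layout):
        digits = {s: 0 for s in tiny_layout.digit_slots()}
        digits[("DC9", 1, "R")] = 1
        with pytest.raises(AssemblyError):
            assemble_code(digits, tiny_layout)

    def test_codes_by_assay_one_per_replicate(self, layout96):
        totals = [WellColorValue(a, 0, 0, 0, 317) for a in layout96.well_map]
        diffs = compute_differences(totals, layout96)
        codes = codes_by_assay(diffs, layout96)
        assert len(codes) == 3
        assert all(c.digits == "0" * 48 for c in codes)


class TestCounting:
    @given(st.lists(st.sampled_from("01"), min_size=1, max_size=64))
    @settings(max_examples=100, deadline=None)
    def test_count_matches_popcount_and_complement(self, bits):
        code = BinaryCode("".join(bits))
        k = sum(int(b) for b in bits)
        assert count_color_changes(code) == k
        flipped = BinaryCode("".join("1" if b == "0" else "0" for b in bits))
        assert count_color_changes(flipped) == len(bits) - k


class TestMatching:
    def lib(self, *codes):
        return CodeLibrary(
            [LibraryEntry(f"analyte{i}", None, BinaryCode(c)) for i, c in enumerate(codes)]
        )

    def test_verbatim_member_matches_at_distance_zero(self):
        lib = self.lib("0000", "1111")
        res = match_code(BinaryCode("1111"), lib)
        assert res.distance == 0
        assert [e.analyte for e in res.best_matches] == ["analyte1"]

    def test_nearest_by_hamming(self):
        lib = self.lib("0000", "1111")
        res = match_code(BinaryCode("0001"), lib)
        assert res.distance == 1
        assert [e.analyte for e in res.best_matches] == ["analyte0"]

    def test_ties_reported_not_broken(self):
        lib = self.lib("0000", "0011")
        res = match_code(BinaryCode("0001"), lib)
        assert res.distance == 1
        assert len(res.best_matches) == 2

    def test_self_distance_zero_property(self):
        for c in ("0", "10101", "1" * 48):
            assert hamming(BinaryCode(c), BinaryCode(c)) == 0

    def test_empty_library_and_length_mismatch(self):
        with pytest.raises(EmptyLibraryError):
            match_code(BinaryCode("0000"), CodeLibrary([]))
        with pytest.raises(CompatibilityError):
            match_code(BinaryCode("000"), self.lib("0000"))

    def test_library_json_roundtrip(self, tmp_path):
        lib = CodeLibrary(
            [LibraryEntry("ketamine", 100.0, BinaryCode("0110")),
             LibraryEntry("phenylalanine", None, BinaryCode("1001"))]
        )
        p = tmp_path / "lib.json"
        lib.to_json(p)
        again = CodeLibrary.from_json(p)
        assert again.entries == lib.entries

    def test_mixed_length_library_rejected(self):
        with pytest.raises(CompatibilityError):
            CodeLibrary([
                LibraryEntry("a", None, BinaryCode("00")),
                LibraryEntry("b", None, BinaryCode("000")),
            ])
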