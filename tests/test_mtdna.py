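"""mtDNA heteroplasmy filtering, list matching and inheritance assignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodx.io import default_data_path, read_pathogenic_mtdna
from mitodx.mtdna import MtdnaQcConfig, analyse_mtdna, filter_mtdna_calls, match_pathogenic, mtdna_inheritance
from mitodx.types import CuratedLists, MtdnaCall


def call(pos=8969, ref="G", alt="A", af=50.0, depth=2000, fwd=None, rev=None, sample="P1"):
    per_strand = max(1, round(depth * af / 200.0)) if af > 0 else 0
    per_strand = min(per_strand, depth // 2)
    return MtdnaCall(
        position=pos, ref=ref, alt=alt, allele_fraction=af, depth=depth,
        forward_alt_reads=per_strand if fwd is None else fwd,
        reverse_alt_reads=per_strand if rev is None else rev,
        sample_id=sample,
    )


@pytest.fixture(scope="module")
def curated():
    return CuratedLists(
        pathogenic_mtdna=read_pathogenic_mtdna(default_data_path("pathogenic_mtdna.tsv")),
        clinvar_plp=set(),
    )


class TestFilter:
    def test_below_one_percent_removed(self):
        assert filter_mtdna_calls([call(af=0.5)]) == []

    def test_retained_at_14_percent_with_balanced_strands(self):
        kept = filter_mtdna_calls([call(pos=8618, ref="T", alt="TT", af=14.0)])
        assert len(kept) == 1

    def test_one_strand_pile_removed(self):
        assert filter_mtdna_calls([call(af=30.0, fwd=600, rev=0)]) == []

    def test_low_depth_removed(self):
        assert filter_mtdna_calls([call(af=30.0, depth=50, fwd=7, rev=8)]) == []

    def test_pure_restriction_and_idempotent(self):
        rng = np.random.default_rng(11)
        calls = [
            call(pos=int(rng.integers(1, 16570)), af=float(rng.uniform(0, 100)),
                 depth=int(rng.integers(10, 5000)), fwd=0 if rng.random() < 0.2 else None)
            for _ in range(200)
        ]
        # fix up strand counts that the helper may have set inconsistently
        kept = filter_mtdna_calls(calls)
        assert all(c in calls for c in kept)
        assert filter_mtdna_calls(kept) == kept

    def test_lowering_threshold_only_adds_calls(self):
        calls = [call(af=a) for a in (0.2, 0.7, 1.0, 3.0, 40.0)]
        strict = {c.allele_fraction for c in filter_mtdna_calls(calls, MtdnaQcConfig(min_heteroplasmy=1.0))}
        loose = {c.allele_fraction for c in filter_mtdna_calls(calls, MtdnaQcConfig(min_heteroplasmy=0.5))}
        assert strict <= loose


class TestMatch:
    def test_listed_heteroplasmic_variant_found(self, curated):
        findings = match_pathogenic([call(pos=8969, ref="G", alt="A", af=84.0)], curated)
        assert len(findings) == 1
        assert findings[0].gene == "MT-ATP6"
        assert not findings[0].homoplasmic

    def test_listed_homoplasmic_variant_flagged(self, curated):
        findings = match_pathogenic([call(pos=14674, ref="T", alt="C", af=100.0)], curated)
        assert findings[0].homoplasmic

    def test_unlisted_call_ignored(self, curated):
        assert match_pathogenic([call(pos=4999, ref="A", alt="G", af=40.0)], curated) == []

    def test_shipped_default_list_has_89_entries(self, curated):
        assert len(curated.pathogenic_mtdna) == 89


class TestInheritance:
    def test_absent_in_mother_is_de_novo(self, curated):
        f = match_pathogenic([call(af=84.0)], curated)[0]
        assert mtdna_inheritance(f, []).inheritance == "de_novo"

    def test_mother_above_threshold_is_maternal(self, curated):
        f = match_pathogenic([call(pos=14674, ref="T", alt="C", af=100.0)], curated)[0]
        mother = call(pos=14674, ref="T", alt="C", af=60.0, sample="MO")
        assert mtdna_inheritance(f, [mother]).inheritance == "maternal"

    def test_no_maternal_sample_is_unknown(self, curated):
        f = match_pathogenic([call(af=84.0)], curated)[0]
        assert mtdna_inheritance(f, None).inheritance == "unknown"

    def test_sub_threshold_mother_is_maternal_with_flag(self, curated):
        f = match_pathogenic([call(pos=8618, ref="T", alt="TT", af=14.0)], curated)[0]
        mother = call(pos=8618, ref="T", alt="TT", af=0.5, sample="MO")
        out = mtdna_inheritance(f, [mother])
        assert out.inheritance == "maternal" and out.mother_subthreshold


@st.composite
def mtdna_calls(draw):
    n = draw(st.integers(0, 20))
    calls = []
    for i in range(n):
        depth = draw(st.integers(1, 5000))
        fwd = draw(st.integers(0, depth))
        rev = draw(st.integers(0, depth - fwd))
        calls.append(
            MtdnaCall(
                position=draw(st.integers(1, 16569)),
                ref="A",
                alt="G",
                allele_fraction=draw(st.floats(0, 100, allow_nan=False)),
                depth=depth,
                forward_alt_reads=fwd,
                reverse_alt_reads=rev,
                sample_id=f"S{i}",
            )
        )
    return calls


@settings(max_examples=200, derandomize=True)
@given(calls=mtdna_calls(), threshold=st.floats(0.1, 10.0, allow_nan=False))
def test_filter_properties_hold_for_arbitrary_calls(calls, threshold):
    """Restriction, idempotence, and monotonicity in the threshold."""
    qc = MtdnaQcConfig(min_heteroplasmy=threshold)
    kept = filter_mtdna_calls(calls, qc)
    assert all(c in calls for c in kept)
    assert filter_mtdna_calls(kept, qc) == kept
    looser = filter_mtdna_calls(calls, MtdnaQcConfig(min_heteroplasmy=threshold / 2))
    assert set(map(id, kept)) <= set(map(id, looser))


def test_full_analysis_path(curated):
    proband = [call(af=84.0), call(pos=5, ref="A", alt="C", af=0.3)]
    findings = analyse_mtdna(proband, [], curated)
    assert [f.inheritance for f in findings] == ["de_novo"]
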