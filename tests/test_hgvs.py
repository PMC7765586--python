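"""Parser behaviour on the COSMIC dialect of HGVS change strings."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrnspec.hgvs import (
    AA1,
    CdnaKind,
    MalformedInputError,
    ProteinChange,
    ProteinKind,
    format_cdna_change,
    format_protein_change,
    parse_cdna_change,
    parse_protein_change,
    predicted_stop_residue,
)


@pytest.mark.parametrize("s,kind,pos,ref,alt,offset", [
    # hotspot frameshift alleles, with and without prefix/offset/case
    ("N511Ifs*13", ProteinKind.FRAMESHIFT, 511, "N", "I", 13),
    ("p.N511fs*13", ProteinKind.FRAMESHIFT, 511, "N", "", 13),
    ("N511LFS*13", ProteinKind.FRAMESHIFT, 511, "N", "L", 13),
    ("K722Rfs*14", ProteinKind.FRAMESHIFT, 722, "K", "R", 14),
    ("K722Gfs*5", ProteinKind.FRAMESHIFT, 722, "K", "G", 5),
    ("R466Gfs*18", ProteinKind.FRAMESHIFT, 466, "R", "G", 18),
    ("R466Kfs*5", ProteinKind.FRAMESHIFT, 466, "R", "K", 5),
    ("R551Gfs*8", ProteinKind.FRAMESHIFT, 551, "R", "G", 8),
    ("R551Kfs*5", ProteinKind.FRAMESHIFT, 551, "R", "K", 5),
    ("K357Nfs*3", ProteinKind.FRAMESHIFT, 357, "K", "N", 3),
    ("H358Tfs*8", ProteinKind.FRAMESHIFT, 358, "H", "T", 8),
    ("R466fs", ProteinKind.FRAMESHIFT, 466, "R", "", None),
    # stop gains, including legacy "X"
    ("Q689*", ProteinKind.NONSENSE, 689, "Q", "*", None),
    ("p.Q689X", ProteinKind.NONSENSE, 689, "Q", "*", None),
    # missense
    ("E185Q", ProteinKind.MISSENSE, 185, "E", "Q", None),
    ("K722R", ProteinKind.MISSENSE, 722, "K", "R", None),
    ("R466K", ProteinKind.MISSENSE, 466, "R", "K", None),
    ("R555K", ProteinKind.MISSENSE, 555, "R", "K", None),
    # synonymous, "=" and identity-substitution spellings
    ("L34=", ProteinKind.SYNONYMOUS, 34, "L", "=", None),
    ("D399=", ProteinKind.SYNONYMOUS, 399, "D", "=", None),
    ("P672=", ProteinKind.SYNONYMOUS, 672, "P", "=", None),
    ("A1A", ProteinKind.SYNONYMOUS, 1, "A", "=", None),
    # in-frame events
    ("p.K45del", ProteinKind.INFRAME_DELETION, 45, "K", "", None),
    ("p.K45dup", ProteinKind.INFRAME_INSERTION, 45, "K", "", None),
])
def test_parse_protein_change(s, kind, pos, ref, alt, offset):
    p = parse_protein_change(s)
    assert p.kind is kind
    assert p.position == pos
    assert p.ref_residue == ref
    assert p.alt_residue == alt
    assert p.fs_stop_offset == offset


@pytest.mark.parametrize("s", ["?", "p.?", "c.1532del", "gibberish", "p.12"])
def test_unrecognised_protein_syntax_is_unknown_not_dropped(s):
    p = parse_protein_change(s)
    assert p.kind is ProteinKind.UNKNOWN
    assert p.raw == s


def test_empty_protein_string_is_malformed():
    with pytest.raises(MalformedInputError):
        parse_protein_change("")
    with pytest.raises(MalformedInputError):
        parse_protein_change("   ")


@pytest.mark.parametrize("s,kind,start,end,ref,alt,offset", [
    ("c.2165A>G", CdnaKind.SUBSTITUTION, 2165, 2165, "A", "G", None),
    ("c.1652G>A", CdnaKind.SUBSTITUTION, 1652, 1652, "G", "A", None),
    ("c.1532del", CdnaKind.DELETION, 1532, 1532, "", "", None),
    ("c.1396del", CdnaKind.DELETION, 1396, 1396, "", "", None),
    ("c.1651del", CdnaKind.DELETION, 1651, 1651, "", "", None),
    ("c.2164_2165del", CdnaKind.DELETION, 2164, 2165, "", "", None),
    ("c.1396dup", CdnaKind.DUPLICATION, 1396, 1396, "", "", None),
    ("c.1651dup", CdnaKind.DUPLICATION, 1651, 1651, "", "", None),
    ("1651dup", CdnaKind.DUPLICATION, 1651, 1651, "", "", None),
    ("c.100_101insA", CdnaKind.INSERTION, 100, 101, "", "A", None),
    ("c.100delinsAT", CdnaKind.DELINS, 100, 100, "", "AT", None),
    ("c.123+5G>A", CdnaKind.INTRONIC_OR_UTR, 123, 123, "", "", 5),
    ("c.124-2A>G", CdnaKind.INTRONIC_OR_UTR, 124, 124, "", "", -2),
    ("c.*45A>G", CdnaKind.INTRONIC_OR_UTR, 45, 45, "", "", None),
    ("c.-12C>T", CdnaKind.INTRONIC_OR_UTR, 12, 12, "", "", None),
])
def test_parse_cdna_change(s, kind, start, end, ref, alt, offset):
    c = parse_cdna_change(s)
    assert c.kind is kind
    assert (c.start, c.end) == (start, end)
    assert c.ref_base == ref
    assert c.alt_base == alt
    assert c.intron_offset == offset


def test_empty_cdna_string_is_malformed():
    with pytest.raises(MalformedInputError):
        parse_cdna_change("")


def test_cdna_unknown_preserves_raw():
    c = parse_cdna_change("c.?")
    assert c.kind is CdnaKind.UNKNOWN and c.raw == "c.?"


@pytest.mark.parametrize("pos,offset,expected", [
    (511, 13, 523),
    (722, 14, 735),
    (100, 1, 100),  # stop at the mutated residue itself
])
def test_predicted_stop_residue(pos, offset, expected):
    p = parse_protein_change(f"K{pos}Rfs*{offset}")
    assert predicted_stop_residue(p) == expected


def test_predicted_stop_rejects_non_frameshift():
    with pytest.raises(ValueError):
        predicted_stop_residue(parse_protein_change("E185Q"))
    with pytest.raises(ValueError):
        predicted_stop_residue(parse_protein_change("N511fs"))


def test_frameshift_requires_fs_token():
    # invariant: no frameshift classification without a parseable "fs"
    for s in ["E185Q", "Q689*", "L34=", "K45del", "nonsense"]:
        assert parse_protein_change(s).kind is not ProteinKind.FRAMESHIFT


def test_invariant_fields_are_enforced():
    with pytest.raises(ValueError):
        ProteinChange(raw="x", kind=ProteinKind.NONSENSE, position=5,
                      ref_residue="Q", alt_residue="Q")
    with pytest.raises(ValueError):
        ProteinChange(raw="x", kind=ProteinKind.MISSENSE, position=5,
                      ref_residue="Q", alt_residue="R", fs_stop_offset=3)
    with pytest.raises(ValueError):
        ProteinChange(raw="x", kind=ProteinKind.MISSENSE, position=0,
                      ref_residue="Q", alt_residue="R")


# --- round-trip property over a generated grammar sample -------------------

aa = st.sampled_from(AA1)
pos = st.integers(min_value=1, max_value=2000)


@st.composite
def protein_strings(draw):
    kind = draw(st.sampled_from(
        ["missense", "nonsense", "synonymous", "frameshift", "del", "dup"]))
    r, p = draw(aa), draw(pos)
    if kind == "missense":
        return f"p.{r}{p}{draw(aa.filter(lambda x: x != r))}"
    if kind == "nonsense":
        return f"{r}{p}*"
    if kind == "synonymous":
        return f"{r}{p}="
    if kind == "frameshift":
        alt = draw(st.sampled_from(["", draw(aa)]))
        off = draw(st.one_of(st.none(), st.integers(1, 60)))
        return f"p.{r}{p}{alt}fs" + (f"*{off}" if off else "")
    return f"{r}{p}{kind}"


@settings(max_examples=300, derandomize=True)
@given(protein_strings())
def test_protein_round_trip(s):
    """format(parse(s)) re-parses to a record equal on all semantic fields."""
    p1 = parse_protein_change(s)
    p2 = parse_protein_change(format_protein_change(p1))
    assert p1 == p2  # raw excluded from equality by construction


@st.composite
def cdna_strings(draw):
    kind = draw(st.sampled_from(
        ["sub", "del", "dup", "ins", "delins", "intron"]))
    start = draw(st.integers(1, 5000))
    base = st.sampled_from("ACGT")
    if kind == "sub":
        b = draw(base)
        return f"c.{start}{b}>{draw(base.filter(lambda x: x != b))}"
    if kind == "intron":
        off = draw(st.integers(-50, 50).filter(lambda x: x != 0))
        return f"c.{start}{off:+d}G>A"
    end = draw(st.integers(start, start + 10))
    span = f"{start}" if end == start else f"{start}_{end}"
    if kind == "del":
        return f"c.{span}del"
    if kind == "dup":
        return f"c.{span}dup"
    if kind == "ins":
        return f"c.{start}_{start + 1}ins{draw(base)}"
    return f"c.{span}delins{draw(base)}{draw(base)}"


@settings(max_examples=300, derandomize=True)
@given(cdna_strings())
def test_cdna_round_trip(s):
    c1 = parse_cdna_change(s)
    c2 = parse_cdna_change(format_cdna_change(c1))
    assert c1 == c2


@settings(max_examples=200, derandomize=True)
@given(st.one_of(protein_strings(), st.text(min_size=1).filter(str.strip)))
def test_classification_is_total_and_single(s):
    """Every non-empty input gets exactly one kind (partition property)."""
    p = parse_protein_change(s)
    assert isinstance(p.kind, ProteinKind)
    assert dataclasses.replace(p).kind is p.kind
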