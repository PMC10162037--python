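import random

import pytest

from patriage import (
    DEFAULT_KEYWORDS,
    DEFAULT_TEMPLATES_RAW,
    KeywordPolicy,
    Section,
    TDL,
    IDGFamily,
    TargetEntry,
    ValidationError,
    compile_templates,
    default_templates,
    detect_bioactivity_tables,
    find_target_mentions,
    normalize_text,
)
from patriage.annotate import write_mentions_tsv

from bruteforce import brute_force_mentions
from conftest import make_doc


# ---------------------------------------------------------------------------
# table keyword detection


@pytest.mark.parametrize(
    "cell, expected_keywords",
    [
        ("IC50 (nM)", ["IC50"]),
        ("Kinase assay results", []),  # "Ki" embedded in a token
        ("NIC50", []),  # keyword embedded in a longer token
        ("IC500", []),  # digit flank breaks the token boundary
        ("IC50-value", ["IC50"]),  # hyphen is a boundary
        ("(IC50)", ["IC50"]),
        ("ic50", ["IC50"]),  # long keywords are case-insensitive
        ("ki = 40 nM", []),  # Ki is case-sensitive
        ("KD", []),  # so is Kd
        ("Ki = 40 nM", ["Ki"]),
        ("Kd 12 nM", ["Kd"]),
        ("IC 50", ["IC 50"]),
        ("IC 50", ["IC 50"]),  # NBSP collapses to a single space
        ("concentration  to\tinhibit", ["concentration to inhibit"]),
        ("pIC50 7.2", ["pIC50"]),  # bare IC50 does NOT also fire inside pIC50
    ],
)
def test_keyword_detection_in_single_cell(cell, expected_keywords):
    doc = make_doc(table_cells=[cell])
    hits = detect_bioactivity_tables(doc)
    assert [h.keyword for h in hits] == expected_keywords


def test_minus_log_cell_matches_both_long_and_embedded_keyword():
    # the parenthesis is a token boundary, so IC50 fires inside −log(IC50)
    doc = make_doc(table_cells=["−log(IC50)"])
    kws = {h.keyword for h in detect_bioactivity_tables(doc)}
    assert "−log(IC50)" in kws and "IC50" in kws


def test_ascii_hyphen_accepted_for_minus_log():
    doc = make_doc(table_cells=["-log(EC50)"])
    kws = {h.keyword for h in detect_bioactivity_tables(doc)}
    assert "−log(EC50)" in kws


def test_keywords_in_description_produce_no_hits():
    doc = make_doc(description="the measured IC50 = 3 nM for compound 7")
    assert detect_bioactivity_tables(doc) == []


def test_hit_offsets_locate_keyword_in_normalized_cell():
    doc = make_doc(table_cells=["assay  result:  IC50 = 3"])
    (hit,) = detect_bioactivity_tables(doc)
    norm = normalize_text("assay  result:  IC50 = 3")
    assert norm[hit.char_offset : hit.char_offset + 4] == "IC50"
    assert hit.cell_index == 0 and hit.table_id == "tbl-1"


def test_keyword_policy_validates_case_sensitive_subset():
    with pytest.raises(ValidationError):
        KeywordPolicy(keywords=("IC50",), case_sensitive_short=frozenset({"Ki"}))
    with pytest.raises(ValidationError):
        KeywordPolicy(keywords=())


# ---------------------------------------------------------------------------
# phrase templates


def test_default_template_set_size():
    assert len(DEFAULT_TEMPLATES_RAW) == 35
    # four alternation groups expand to one extra pattern each
    assert len(default_templates()) == 39


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Blocks|block X", ["Blocks X", "block X"]),
        ("Inhibitors of X", ["Inhibitors of X"]),
        (
            "Antibodies recognis|zing X",
            ["Antibodies recognising X", "Antibodies recognizing X"],
        ),
        ("Ligand|ligands for X", ["Ligand for X", "ligands for X"]),
        ("X ligand|ligands", ["X ligand", "X ligands"]),
    ],
)
def test_alternation_expansion(raw, expected):
    assert [t.pattern for t in compile_templates([raw])] == expected


@pytest.mark.parametrize("raw", ["Inhibitors of", "X binds X", "Y inhibitors"])
def test_template_without_single_placeholder_rejected(raw):
    with pytest.raises(ValidationError):
        compile_templates([raw])


# ---------------------------------------------------------------------------
# target mentions


def test_title_mention_via_template(small_dictionary):
    doc = make_doc(title="Inhibitors of LATS1")
    (m,) = find_target_mentions(doc, small_dictionary)
    assert m.target_id == "T1"
    assert m.template.pattern == "Inhibitors of X"
    assert m.section is Section.title
    assert normalize_text(doc.title)[m.start : m.end] == "Inhibitors of LATS1"


def test_bare_name_without_template_context_is_not_a_mention(small_dictionary):
    doc = make_doc(abstract="LATS1 is a Ser/Thr kinase")
    assert find_target_mentions(doc, small_dictionary) == []


def test_claim_mention_records_claim_index(small_dictionary):
    doc = make_doc(
        claims=("A pharmaceutical composition.",
                "Use of compounds that interact with GPR6 in therapy.")
    )
    (m,) = find_target_mentions(doc, small_dictionary)
    assert m.section is Section.claims and m.claim_index == 1
    assert m.template.raw == "Compounds that interact with X"
    norm = normalize_text(doc.claims[1])
    assert norm[m.start : m.end].lower() == "compounds that interact with gpr6"


def test_unlisted_synonym_is_missed(small_dictionary):
    # the dictionary knows "Cholesterol 24-hydroxylase", not "CH24H"
    doc = make_doc(description="novel CH24H inhibitors are disclosed")
    assert find_target_mentions(doc, small_dictionary) == []


def test_name_hyphen_space_variants_match(small_dictionary):
    doc = make_doc(description="potent Cholesterol 24 hydroxylase inhibitors")
    (m,) = find_target_mentions(doc, small_dictionary)
    assert m.target_id == "T3" and m.matched_name == "Cholesterol 24-hydroxylase"


def test_short_symbol_is_case_sensitive(small_dictionary):
    hit = make_doc(title="KIT inhibitors")
    miss = make_doc(title="kit inhibitors")
    assert find_target_mentions(hit, small_dictionary, understudied_only=False)
    assert not find_target_mentions(miss, small_dictionary, understudied_only=False)


def test_understudied_filter_excludes_tclin_targets(small_dictionary):
    doc = make_doc(title="KIT inhibitors")  # KIT is Tclin in the fixture
    assert find_target_mentions(doc, small_dictionary) == []
    assert find_target_mentions(doc, small_dictionary, understudied_only=False)


def test_long_names_match_case_insensitively(small_dictionary):
    doc = make_doc(title="INHIBITORS OF lats1")
    (m,) = find_target_mentions(doc, small_dictionary)
    assert m.target_id == "T1"


def test_phrase_embedded_in_longer_token_is_rejected(small_dictionary):
    doc = make_doc(title="Inhibitors of LATS12")  # trailing digit breaks boundary
    assert find_target_mentions(doc, small_dictionary) == []


def test_overlapping_mentions_of_different_targets_all_reported():
    dictionary = [
        TargetEntry("TA", "fatty acid synthase", "FASN", TDL.Tbio, IDGFamily.other),
        TargetEntry("TB", "acid synthase", "QQQQ1", TDL.Tdark, IDGFamily.other),
    ]
    doc = make_doc(title="Inhibitors of fatty acid synthase")
    ids = {m.target_id for m in find_target_mentions(doc, dictionary)}
    # no longest-match suppression: the shorter name is NOT reported here
    # (its phrase "Inhibitors of acid synthase" does not occur), but the
    # bare-name overlap inside another template does fire for both:
    doc2 = make_doc(title="fatty acid synthase inhibitors and acid synthase inhibitors")
    ids2 = {m.target_id for m in find_target_mentions(doc2, dictionary)}
    assert ids == {"TA"}
    assert ids2 == {"TA", "TB"}


def test_no_cross_section_matches(small_dictionary):
    # template split across the abstract/description boundary must not match
    doc = make_doc(abstract="novel Inhibitors of", description="LATS1 and salts thereof")
    assert find_target_mentions(doc, small_dictionary) == []


def test_deleting_a_section_removes_exactly_its_mentions(small_dictionary):
    doc = make_doc(
        title="Inhibitors of LATS1",
        abstract="Targeting GPR6 with small molecules",
        description="Modulators of LATS1 and uses thereof",
        claims=("LATS1 binding agents.",),
    )
    full = find_target_mentions(doc, small_dictionary)
    without_abstract = find_target_mentions(
        make_doc(title=doc.title, description=doc.description, claims=doc.claims),
        small_dictionary,
    )
    kept = [m for m in full if m.section is not Section.abstract]
    assert [(m.section, m.start, m.end, m.target_id) for m in kept] == [
        (m.section, m.start, m.end, m.target_id) for m in without_abstract
    ]
    assert len(full) > len(without_abstract)


def test_annotation_output_is_deterministic(tmp_path, small_dictionary):
    doc = make_doc(
        title="Inhibitors of LATS1",
        abstract="Targeting GPR6",
        claims=("Compounds that interact with GPR6.", "LATS1 modulators."),
    )
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_mentions_tsv(find_target_mentions(doc, small_dictionary), p1)
    write_mentions_tsv(find_target_mentions(doc, small_dictionary), p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# oracle equivalence


ORACLE_RAW_TEMPLATES = [
    "Inhibitors of X",
    "X inhibitors",
    "Compounds that interact with X",
    "Anti-X antibody",
    "Modulating the X",
]
# the same phrases as naive (prefix, suffix) pairs for the brute-force scan
ORACLE_PAIRS = [
    ("Inhibitors of ", ""),
    ("", " inhibitors"),
    ("Compounds that interact with ", ""),
    ("Anti-", " antibody"),
    ("Modulating the ", ""),
]

ORACLE_ENTRIES = [
    TargetEntry("T1", "orphan synthase 1", "STG1", TDL.Tbio, IDGFamily.other),
    TargetEntry("T2", "beta-2 adrenoceptor homolog", "KIT", TDL.Tdark, IDGFamily.gpcr),
    TargetEntry("T3", "LATS1", "LATS1", TDL.Tbio, IDGFamily.kinase),
]

_VOCAB = [
    "Inhibitors", "of", "inhibitors", "alpha", "beta", "STG1", "STG12",
    "stg1", "Modulating", "the", "granule", "Anti-STG1", "antibody",
    "Compounds", "that", "interact", "with", "KIT", "kit", "Kit",
    "LATS1", "lats1", "orphan", "synthase", "1", "2", "beta-2",
    "adrenoceptor", "homolog", "Anti-KIT", "Anti-LATS1", "anti-lats1",
]


def _random_words(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_VOCAB) for _ in range(n))


def test_production_matcher_equals_brute_force_oracle(small_dictionary):
    """Exhaustive naive scan and production matcher agree on random text."""
    templates = compile_templates(ORACLE_RAW_TEMPLATES)
    rng = random.Random(20240917)
    n_docs = 120
    n_with_mentions = 0
    for i in range(n_docs):
        doc = make_doc(
            patent_id=f"P{i}",
            title=_random_words(rng, rng.randint(0, 8)),
            abstract=_random_words(rng, rng.randint(0, 15)),
            description=_random_words(rng, rng.randint(0, 25)),
            claims=tuple(
                _random_words(rng, rng.randint(1, 12))
                for _ in range(rng.randint(0, 2))
            ),
        )
        got = {
            (
                m.section.value,
                m.claim_index,
                m.target_id,
                m.matched_name,
                ORACLE_RAW_TEMPLATES.index(m.template.raw),
                m.start,
                m.end,
            )
            for m in find_target_mentions(
                doc, ORACLE_ENTRIES, templates, understudied_only=False
            )
        }
        expected = set()
        sections = [
            ("title", None, doc.title),
            ("abstract", None, doc.abstract),
            ("description", None, doc.description),
        ] + [("claims", ci, c) for ci, c in enumerate(doc.claims)]
        for sec, ci, text in sections:
            for tid, name, pi, start, end in brute_force_mentions(
                text, ORACLE_ENTRIES, ORACLE_PAIRS
            ):
                expected.add((sec, ci, tid, name, pi, start, end))
        assert got == expected, f"doc {i} disagrees"
        n_with_mentions += bool(got)
    # the random corpus must actually exercise the matcher
    assert n_with_mentions > 20
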