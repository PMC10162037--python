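import pytest

from patriage import IDGFamily, PatentDocument, PatentTable, TDL, TargetEntry


@pytest.fixture
def kinase_target() -> TargetEntry:
    return TargetEntry("T1", "LATS1", "LATS1", TDL.Tbio, IDGFamily.kinase)


@pytest.fixture
def gpcr_target() -> TargetEntry:
    return TargetEntry("T2", "G protein-coupled receptor 6", "GPR6", TDL.Tdark, IDGFamily.gpcr)


@pytest.fixture
def small_dictionary(kinase_target, gpcr_target) -> list[TargetEntry]:
    return [
        kinase_target,
        gpcr_target,
        TargetEntry("T3", "Cholesterol 24-hydroxylase", "CYP46A1", TDL.Tbio, IDGFamily.other),
        TargetEntry("T4", "mast/stem cell growth factor receptor", "KIT", TDL.Tclin, IDGFamily.kinase),
    ]


def make_doc(
    patent_id="P1",
    family_id="F1",
    title="",
    abstract="",
    description="",
    claims=(),
    table_cells=None,
    codes=("A61K 31/00",),
) -> PatentDocument:
    tables = ()
    if table_cells is not None:
        tables = (PatentTable("tbl-1", tuple(table_cells)),)
    return PatentDocument(
        patent_id=patent_id,
        family_id=family_id,
        classification_codes=tuple(codes),
        title=title,
        abstract=abstract,
        description=description,
        claims=tuple(claims),
        tables=tables,
    )
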