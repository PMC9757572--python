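import pytest
from hypothesis import settings

from readbridge.terminology import CodeSystem, Concept, Ontology

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def icd10_dict() -> Ontology:
    """A small ICD-10 dictionary with categories, leaves and an
    "unspecified" child, shaped like the meningitis/rubella examples."""
    onto = Ontology(system=CodeSystem.ICD10)
    rows = [
        ("A87", "Viral meningitis", None),
        ("A870", "Enteroviral meningitis", "A87"),
        ("A879", "Viral meningitis, unspecified", "A87"),
        ("B06", "Rubella", None),
        ("B069", "Rubella without complication", "B06"),
        ("A08", "Viral intestinal infections", None),
        ("A080", "Rotaviral enteritis", "A08"),
        ("K62", "Other diseases of anus and rectum", None),
        ("K620", "Anal polyp", "K62"),
        ("K621", "Rectal polyp", "K62"),
        ("E70", "Disorders of aromatic amino-acid metabolism", None),
        ("E702", "Disorders of tyrosine metabolism", "E70"),
        ("M19", "Other and unspecified osteoarthritis", None),
        ("M190", "Primary osteoarthritis of other joints", "M19"),
    ]
    for code, desc, parent in rows:
        onto.add(Concept(CodeSystem.ICD10, code, desc, parent_code=parent))
    return onto
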