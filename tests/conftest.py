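import hypothesis
import pytest
from hypothesis import strategies as st

from mrharmonize import VariantRecord, table2_fixture

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def table2():
    """Worked-example datasets: (exposure, outcome, proxies)."""
    return table2_fixture()


# --- hypothesis strategies shared across test modules ----------------------

alleles = st.sampled_from("ACGT")

allele_pairs = st.tuples(alleles, alleles).filter(lambda p: p[0] != p[1])

def _nonpal(pair):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return comp[pair[0]] != pair[1]


nonpal_pairs = allele_pairs.filter(_nonpal)

betas = st.floats(min_value=-2.0, max_value=2.0, allow_nan=False)
nonzero_betas = betas.filter(lambda b: abs(b) > 1e-6)
ses = st.floats(min_value=1e-3, max_value=1.0, allow_nan=False)
eafs = st.floats(min_value=0.02, max_value=0.98, allow_nan=False)


@st.composite
def variant_records(draw, pair_strategy=allele_pairs, eaf_optional=True,
                    beta_strategy=betas):
    ea, oa = draw(pair_strategy)
    eaf = draw(st.none() | eafs) if eaf_optional else draw(eafs)
    return VariantRecord(
        variant_id=f"rs{draw(st.integers(1, 10 ** 6))}",
        effect_allele=ea,
        other_allele=oa,
        beta=draw(beta_strategy),
        se=draw(ses),
        eaf=eaf,
    )
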