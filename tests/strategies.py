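"""Shared hypothesis strategies for random architectures and genotypes."""

from hypothesis import strategies as st

from karyosort import DiploidGenotype, FusionArchitecture


@st.composite
def architectures(draw, max_units: int = 80):
    n_units = draw(st.integers(min_value=1, max_value=max_units))
    n_sites = draw(st.integers(min_value=0, max_value=n_units // 2))
    sites = tuple((2 * i + 1, 2 * i + 2) for i in range(n_sites))
    return FusionArchitecture(n_units, sites)


@st.composite
def genotypes(draw, max_units: int = 80):
    arch = draw(architectures(max_units=max_units))
    allele = st.integers(min_value=0, max_value=1)
    alleles = tuple(
        (draw(allele), draw(allele)) for _ in range(arch.n_sites)
    )
    return DiploidGenotype(arch, alleles)
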