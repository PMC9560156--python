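import pytest

from prototroph.pathway import (
    ECNumber,
    PathwayCatalog,
    PathwayVariant,
    ReactionStep,
    load_packaged_catalog,
)


def make_step(step_id, ecs, substrate, product):
    return ReactionStep(
        step_id=step_id,
        ec_options=frozenset(ECNumber(e) for e in ecs),
        substrate=substrate,
        product=product,
    )


def make_chain_variant(variant_id, amino_acid, ec_lists, genes=()):
    """A linear variant whose metabolite names are auto-chained."""
    steps = tuple(
        make_step(f"s{i}", ecs, f"m{i}", f"m{i + 1}")
        for i, ecs in enumerate(ec_lists)
    )
    return PathwayVariant(
        variant_id=variant_id,
        amino_acid=amino_acid,
        steps=steps,
        gene_symbols=frozenset(genes),
    )


@pytest.fixture(scope="session")
def catalog():
    return load_packaged_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Three variants over two amino acids, small enough to enumerate."""
    return PathwayCatalog(
        (
            make_chain_variant(
                "valA", "Val", [["1.1.1.1"], ["2.2.2.2"], ["3.3.3.3"]]
            ),
            make_chain_variant(
                "valB", "Val", [["1.1.1.1"], ["4.4.4.4"]]
            ),
            make_chain_variant(
                "alaA", "Ala", [["5.5.5.5"]]
            ),
        )
    )
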