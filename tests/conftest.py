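"""Shared fixtures: all test data is generated programmatically."""

import pytest

import lctox as lx


@pytest.fixture(scope="session")
def tiny_germline():
    """The 8-residue worked-example germline."""
    return lx.GermlineRecord("GL8", "SYVLTQPP", tuple(str(i) for i in range(1, 9)))


@pytest.fixture(scope="session")
def toy_germlines():
    return {g.germline_id: g for g in lx.TOY_GERMLINES}


@pytest.fixture(scope="session")
def toy_scheme_map():
    return lx.toy_scheme()


@pytest.fixture(scope="session")
def planted_spec():
    """Two strong discriminative mutations on a modest repertoire."""
    return lx.SimSpec(
        n_tox=150, n_nox=150, background_sm_rate=0.03, seed=11,
        planted_effects=(lx.PlantedEffect(49, "A", 0.5, 0.05),
                         lx.PlantedEffect(60, "W", 0.4, 0.05)),
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_spec, toy_germlines):
    records, truth = lx.generate_repertoire(planted_spec)
    encodings, scheme = lx.encode_dataset(records, toy_germlines)
    labels = {r.sequence_id: r.label for r in records}
    return {"records": records, "truth": truth, "encodings": encodings,
            "scheme": scheme, "labels": labels,
            "universe": sorted(set(scheme.values()))}


@pytest.fixture(scope="session")
def planted_matrix(planted_dataset):
    return lx.assemble_matrix(planted_dataset["encodings"], ("AMP",),
                              labels=planted_dataset["labels"],
                              position_universe=planted_dataset["universe"])
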