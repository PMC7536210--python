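"""Shared fixtures: small synthetic genomes with truth manifests."""

import warnings

import pytest

from mitocomp.synthetic import (
    GenePlan,
    IntronPlan,
    RepeatPlan,
    SyntheticSpec,
    TandemPlan,
    generate_genome,
)


def small_spec(seed: int = 101, **overrides) -> SyntheticSpec:
    """A compact (~22 kb) genome exercising every feature class."""
    genes = [
        GenePlan("cox1", "core_pcg", 1608, "+"),
        GenePlan("cox2", "core_pcg", 750, "+"),
        GenePlan("cob", "core_pcg", 1179, "-"),
        GenePlan("nad4L", "core_pcg", 270, "+"),
        GenePlan("nad5", "core_pcg", 2016, "+"),
        GenePlan("rps3", "core_pcg", 1482, "+"),
        GenePlan("atp8", "core_pcg", 147, "-"),
        GenePlan("rnl", "rrna", 2400, "+"),
        GenePlan("rns", "rrna", 1400, "+"),
        GenePlan("rnpB", "rnpB", 329, "+"),
        GenePlan("orf300", "orf", 903, "+"),
        GenePlan("trnA", "trna", 72, "+", anticodon="tgc"),
        GenePlan("trnW", "trna", 74, "+", anticodon="tca"),
        GenePlan("trnM", "trna", 72, "+", anticodon="cat"),
        GenePlan("trnM2", "trna", 72, "-", anticodon="cat"),
    ]
    introns = [
        IntronPlan("cox1", 121, 0, 420, "I", orf_length=300),
        IntronPlan("cox1", 250, 2, 380, "I"),
        IntronPlan("cox1", 398, 0, 350, "I"),
        IntronPlan("cob", 130, 0, 400, "I"),
        IntronPlan("rnl", 300, 0, 450, "I"),
    ]
    repeats = [
        RepeatPlan(902, "forward", 100.0),
        RepeatPlan(300, "palindromic", 100.0),
        RepeatPlan(120, "reverse", 100.0),
        RepeatPlan(60, "complemented", 100.0),
    ]
    tandems = [TandemPlan(79, 2), TandemPlan(12, 6)]
    spec = SyntheticSpec(
        length=22_000, genes=genes, introns=introns, repeats=repeats,
        tandems=tandems, seed=seed, genome_id=f"syn{seed}",
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    return spec


@pytest.fixture(scope="session")
def planted():
    """(genome, manifest) for the standard small synthetic genome."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genome, manifest = generate_genome(small_spec())
    return genome, manifest
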