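"""Session fixtures: synthetic library bundles built once per run."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from peacseq.readprep import TagDesign, default_tag_design
from peacseq.simulate import (
    JunctionSpec,
    LibraryParams,
    PlantedSite,
    ReferenceSequence,
    SimTruth,
    generate_reference,
    plant_sites,
    simulate_junction_library,
    simulate_library,
    simulate_wt_control,
)
from peacseq.util import random_dna, spawn_rng


@dataclass
class Bundle:
    ref: ReferenceSequence
    spacer: str
    sites: list[PlantedSite]
    junctions: list[JunctionSpec]
    tag: TagDesign
    prefix: str
    wt_prefix: str
    truth: SimTruth
    wt_truth: SimTruth

    @property
    def sam(self) -> str:
        return self.prefix + "_truth.sam"

    @property
    def wt_sam(self) -> str:
        return self.wt_prefix + "_truth.sam"


@pytest.fixture(scope="session")
def tag() -> TagDesign:
    return default_tag_design()


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory, tag) -> Bundle:
    """The standard end-to-end fixture: 100 kb reference, 1 on-target + 6
    off-targets carrying 1-6 mismatches, 50k error-free read pairs with the
    default random-priming and background rates, plus a 20k-pair WT
    control."""
    d = tmp_path_factory.mktemp("default_bundle")
    seed = 11
    spacer = random_dna(spawn_rng(seed, "spacer"), 20, 0.5)
    ref0 = generate_reference(100_000, 0.41, seed)
    ref, sites = plant_sites(ref0, spacer, 6, [1, 2, 3, 4, 5, 6], seed)
    prefix = str(d / "sample")
    wt_prefix = str(d / "wt")
    truth = simulate_library(
        ref, sites, [], tag, LibraryParams(n_fragments=50_000, seed=seed), prefix)
    wt_truth = simulate_wt_control(
        ref, tag, LibraryParams(n_fragments=20_000, seed=seed + 1), wt_prefix)
    return Bundle(ref, spacer, sites, [], tag, prefix, wt_prefix, truth, wt_truth)


@pytest.fixture(scope="session")
def rp_bundle(tmp_path_factory, tag) -> Bundle:
    """Random-priming stress fixture: 5% mispriming, error-free."""
    d = tmp_path_factory.mktemp("rp_bundle")
    seed = 23
    spacer = random_dna(spawn_rng(seed, "spacer"), 20, 0.5)
    ref0 = generate_reference(100_000, 0.41, seed)
    ref, sites = plant_sites(ref0, spacer, 4, [1, 2, 3, 4], seed)
    prefix = str(d / "sample")
    wt_prefix = str(d / "wt")
    params = LibraryParams(n_fragments=20_000, seed=seed,
                           random_priming_rate=0.05, seq_error_rate=0.0)
    truth = simulate_library(ref, sites, [], tag, params, prefix)
    wt_truth = simulate_wt_control(
        ref, tag, LibraryParams(n_fragments=10_000, seed=seed + 1,
                                random_priming_rate=0.05), wt_prefix)
    return Bundle(ref, spacer, sites, [], tag, prefix, wt_prefix, truth, wt_truth)


@pytest.fixture(scope="session")
def junction_bundle(tmp_path_factory, tag):
    """Receiver + donor with all five join models planted.

    Returns (bundle, junction_prefix, junction_truth): the bundle's own
    library carries the model-(v) junction (the only one visible to tag
    enrichment); the junction library carries all five.
    """
    d = tmp_path_factory.mktemp("junction_bundle")
    seed = 37
    spacer = random_dna(spawn_rng(seed, "spacer"), 20, 0.5)
    ref0 = generate_reference(60_000, 0.45, seed)
    # sites alternate strands; site 0 (receiver) and site 2 (donor) are '+'
    ref, sites = plant_sites(ref0, spacer, 2, [2, 3], seed)
    recv, donor = sites[0], sites[2]
    jx = [
        JunctionSpec(recv, donor, "i", True, 0.10),
        JunctionSpec(recv, donor, "ii", False, 0.10),
        JunctionSpec(recv, donor, "iii", False, 0.10),
        JunctionSpec(recv, donor, "iv", False, 0.10),
        JunctionSpec(recv, donor, "v", True, 0.15),
    ]
    prefix = str(d / "sample")
    wt_prefix = str(d / "wt")
    truth = simulate_library(
        ref, sites, [jx[4]], tag,
        LibraryParams(n_fragments=15_000, seed=seed, random_priming_rate=0.0),
        prefix)
    wt_truth = simulate_wt_control(
        ref, tag, LibraryParams(n_fragments=5_000, seed=seed + 1,
                                random_priming_rate=0.0), wt_prefix)
    bundle = Bundle(ref, spacer, sites, [jx[4]], tag, prefix, wt_prefix,
                    truth, wt_truth)
    jx_prefix = str(d / "junction")
    jx_truth = simulate_junction_library(
        ref, recv, jx, tag, LibraryParams(n_fragments=3_000, seed=seed), jx_prefix)
    return bundle, jx_prefix, jx_truth, jx
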