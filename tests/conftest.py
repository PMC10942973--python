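from dataclasses import replace

import pytest

from refchrom.synth_fixtures import (
    PRESETS,
    derive_assembly,
    emit_truth_alignments,
    generate_template,
)


class FixtureBundle:
    """A generated template + derived assembly + truth, ready for tests."""

    def __init__(self, config):
        self.config = config
        self.template, self.gc_targets = generate_template(config)
        self.scaffolds, self.decoys, self.manifest = derive_assembly(
            self.template, config
        )
        self.hits = emit_truth_alignments(self.manifest)
        self.template_lengths = {r.id: len(r.seq) for r in self.template}
        self.template_map = {r.id: r.seq for r in self.template}


@pytest.fixture(scope="session")
def small_bundle():
    """The clean 'small' preset: chimeras, inversions, no decoys."""
    return FixtureBundle(replace(PRESETS["small"], seed=11))


@pytest.fixture(scope="session")
def tiny_bundle():
    return FixtureBundle(replace(PRESETS["tiny"], seed=5))
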