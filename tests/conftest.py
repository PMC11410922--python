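import numpy as np
import pytest

from netperturb import MixedGraph


@pytest.fixture
def chain():
    """X -> M -> Y"""
    return MixedGraph.from_edges(directed=[("X", "M"), ("M", "Y")])


@pytest.fixture
def collider():
    """X -> C <- Y"""
    return MixedGraph.from_edges(directed=[("X", "C"), ("Y", "C")])


@pytest.fixture
def bow():
    """X -> Y with X <-> Y: the canonical non-identifiable structure."""
    return MixedGraph.from_edges(directed=[("X", "Y")], bidirected=[("X", "Y")])


@pytest.fixture
def backdoor():
    """Z -> X -> Y, Z -> Y: classic confounded triangle."""
    return MixedGraph.from_edges(directed=[("Z", "X"), ("X", "Y"), ("Z", "Y")])


@pytest.fixture
def frontdoor():
    """X -> M -> Y with X <-> Y: identifiable only through the mediator."""
    return MixedGraph.from_edges(directed=[("X", "M"), ("M", "Y")], bidirected=[("X", "Y")])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
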