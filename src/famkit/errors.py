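"""Exception hierarchy.

``FamkitError`` is the base for every data/usage error the library raises on
malformed or inconsistent input; the CLI maps it to exit code 2.
"""


class FamkitError(Exception):
    """Base class for all famkit data errors."""


class NewickParseError(FamkitError):
    """Malformed newick/NEXUS input; message names the offending position."""


class TreeStructureError(FamkitError):
    """A tree violates a structural invariant (cycles, duplicate leaves...)."""


class LeafSetError(FamkitError):
    """Leaf-set mismatch between trees or between a tree and a query set."""


class SpeciesMapError(FamkitError):
    """A gene leaf label cannot be mapped to a species."""


class SampleError(FamkitError):
    """A posterior tree sample is empty or internally inconsistent."""


class SimulationError(FamkitError):
    """Invalid simulation inputs (non-ultrametric tree, zero-length branch)."""


class ReconcileError(FamkitError):
    """Reconciliation inputs are inconsistent (unknown species, etc.)."""
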