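"""Exception hierarchy: one base class, one subclass per pipeline stage."""


class PhenodiffError(Exception):
    """Base class for all package errors."""


class OntologyError(PhenodiffError):
    """Malformed ontology input or unresolvable term id."""


class CohortError(PhenodiffError):
    """Invalid case-report data or partition."""


class ComparisonError(PhenodiffError):
    """Degenerate contingency table or inconsistent comparison inputs."""


class InfeasibleCountsError(PhenodiffError):
    """A count fixture violating ancestor monotonicity cannot be realized."""
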