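"""Named exception types raised across the package.

Every distinct user-facing failure mode has its own class so that callers
(and the CLI) can report actionable messages instead of bare ValueErrors.
"""


class OwscoreError(Exception):
    """Base class for all package errors."""


class PedigreeError(OwscoreError):
    """Base class for pedigree validation failures."""


class DuplicateIndividualError(PedigreeError):
    """An individual ID occurs more than once within a family."""


class UnknownParentError(PedigreeError):
    """A parent ID does not refer to any member of the same family."""


class PedigreeCycleError(PedigreeError):
    """The parent graph contains a cycle (an individual is its own ancestor)."""


class SingleParentError(PedigreeError):
    """A member records exactly one parent; founders must record zero, others two."""


class PedigreeOrderError(PedigreeError):
    """Internal ordering failure: a parent appears after its child."""


class EmptyIntersectionError(OwscoreError):
    """No individual is present, complete, in all input sources."""


class RegionError(OwscoreError):
    """A genomic-region filter matched zero variants or cannot be applied."""


class CollinearCovariatesError(OwscoreError):
    """The covariate design matrix is rank-deficient after adding an intercept."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "collinear covariate column(s): " + ", ".join(map(str, self.columns))
        )


class DegenerateTraitError(OwscoreError):
    """The centered trait is identically zero, so the kinship quadratic form vanishes."""


class MonomorphicRegionError(OwscoreError):
    """Every variant in the region is monomorphic in the analyzed sample."""


class DegenerateWeightsError(OwscoreError):
    """The weighted burden has zero variance (V = 0)."""


class SimulationError(OwscoreError):
    """Invalid simulation configuration or infeasible variance partition."""


class AscertainmentError(OwscoreError):
    """No pedigree satisfies the ascertainment rule within the redraw budget."""
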