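"""Exception hierarchy for hfclust.

Every stage raises a subclass of :class:`HfclustError` so callers (and the
pipeline driver) can distinguish pipeline failures from programming errors.
"""


class HfclustError(Exception):
    """Base class for all hfclust errors."""


class SpecError(HfclustError):
    """An invalid synthetic-cohort specification (bad simplex, non-PSD copula...)."""


class PreprocessingError(HfclustError):
    """A preprocessing contract violation (all columns dropped, zero variance...)."""


class ClusteringError(HfclustError):
    """Invalid clustering input (zero feature range, k out of bounds...)."""


class SelectionError(HfclustError):
    """Model selection failure (no admissible configuration)."""


class NoMajorityError(SelectionError):
    """Three-way index split with no majority winner.

    Carries the full per-index tally so the caller can resolve the tie
    explicitly (e.g. via a ``prefer_k`` override).
    """

    def __init__(self, message, tally):
        super().__init__(message)
        self.tally = tally


class NetworkError(HfclustError):
    """Disease-network construction failure (empty subset, zero nodes)."""


class ProfileError(HfclustError):
    """Cluster profiling failure (empty cluster, degenerate test input)."""


class SurvivalError(HfclustError):
    """Survival-analysis failure (bad censor date, non-convergence)."""
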