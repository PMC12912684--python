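"""Exception hierarchy shared across the package."""


class SpermEvalError(Exception):
    """Base class for all package-specific errors."""


class TrackFormatError(SpermEvalError):
    """A trajectory or annotation file does not conform to the expected format."""


class TrackValidationError(SpermEvalError):
    """Parsed data violates a structural invariant (e.g. duplicate label/frame)."""


class UndefinedMetricError(SpermEvalError):
    """A tracking score is mathematically undefined for the given input.

    Raised e.g. when the ground truth holds zero detections (DET, TRA, MOTA)
    or zero edges (LNK, i.e. every ground-truth track is a singleton).
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} is undefined: {reason}")


class UndefinedKinematicError(SpermEvalError):
    """A kinematic parameter is undefined (e.g. velocity of a single detection)."""
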