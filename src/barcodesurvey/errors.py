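"""Exception hierarchy for the barcode survey pipeline."""


class BarcodeSurveyError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(BarcodeSurveyError):
    """Sequences in a dataset do not share a common aligned length."""


class DatasetError(BarcodeSurveyError):
    """Invalid dataset construction (duplicate ids, missing records, empty)."""


class TreeError(BarcodeSurveyError):
    """Invalid tree input or tree/dataset mismatch."""


class SaturationError(BarcodeSurveyError):
    """K2P log-domain violation: observed differences exceed the model ceiling.

    Carries the offending transition and transversion proportions.
    """

    def __init__(self, p: float, q: float):
        self.p = p
        self.q = q
        super().__init__(
            f"K2P saturation: 1-2P-Q={1 - 2 * p - q:.4f}, 1-2Q={1 - 2 * q:.4f} "
            f"(P={p:.4f}, Q={q:.4f})"
        )


class InsufficientOverlapError(BarcodeSurveyError):
    """Too few jointly unambiguous sites to estimate a distance."""


class MissingDistanceError(BarcodeSurveyError):
    """An operation requires complete pairwise distances but some are missing."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        shown = ", ".join(f"{a}~{b}" for a, b in self.pairs[:10])
        more = "" if len(self.pairs) <= 10 else f" (+{len(self.pairs) - 10} more)"
        super().__init__(f"missing pairwise distances: {shown}{more}")


class ConfigError(BarcodeSurveyError):
    """Invalid configuration value."""
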