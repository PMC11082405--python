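"""Exception hierarchy.

Configuration problems (bad editor definitions, malformed CFD tables,
unusable CLI arguments) and data problems (unreadable or inconsistent
inputs) are kept distinct so the command line can map them onto
different exit codes.
"""


class BexploreError(Exception):
    """Base class for all package errors."""


class ConfigError(BexploreError):
    """Malformed or invalid configuration (editor config, CFD table, CLI)."""


class EditorLookupError(ConfigError):
    """Requested editor name is not present in the registry."""


class FormatError(BexploreError):
    """A structurally malformed input file."""


class DataError(BexploreError):
    """Input parses but is inconsistent (e.g. site outside its chromosome)."""


class NonConvertibleEffectError(BexploreError):
    """Observed-scale effect cannot be mapped back to the allelic scale.

    Raised when the denominator of the scale-conversion formula is not
    positive for the supplied (beta_obs, phi, theta); carries the inputs.
    """

    def __init__(self, beta_obs: float, phi: float, theta: float, denom: float):
        self.beta_obs = beta_obs
        self.phi = phi
        self.theta = theta
        self.denom = denom
        super().__init__(
            f"effect-scale conversion denominator is {denom:.6g} <= 0 for "
            f"beta_obs={beta_obs}, phi={phi}, theta={theta}"
        )


class SpecError(BexploreError):
    """A synthetic-fixture specification that cannot be realised."""
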