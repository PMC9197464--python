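"""Exception hierarchy shared across the pipeline.

``InputError`` covers validation failures of user-supplied or generated data
(CLI exit code 2); ``ConvergenceError`` covers numerical non-convergence
(CLI exit code 3).
"""


class PRNetError(Exception):
    """Base class for all pipeline errors."""


class InputError(PRNetError):
    """Invalid, missing or malformed input data or parameters."""


class ConvergenceError(PRNetError):
    """An iterative solver failed to reach its tolerance."""
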