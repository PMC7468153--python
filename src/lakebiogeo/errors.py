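"""Exception hierarchy shared by the whole pipeline.

The CLI maps these onto exit codes: ValidationError -> 2,
DegenerateDataError -> 3.
"""


class ValidationError(ValueError):
    """Malformed or out-of-contract input (bad coordinates, duplicate ids...)."""


class DegenerateDataError(RuntimeError):
    """Structurally valid input on which the requested analysis is undefined
    (e.g. no mountain lakes for an altitude contrast, antipodal centroid)."""
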