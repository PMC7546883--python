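"""Exception types shared across the package.

Plain ``ValueError`` is used for invalid arguments; the classes here mark
domain conditions callers may want to catch specifically.
"""


class EmptyStructureError(ValueError):
    """A structure mask has (or would end up with) zero occupied voxels."""


class IncompatibleGridsError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given inputs (e.g. two empty masks)."""


class ConstraintParseError(ValueError):
    """A clinical constraint string does not match the supported grammar."""
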