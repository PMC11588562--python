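"""Exception types shared across the model modules."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class CapacityError(RuntimeError):
    """A computation exceeds its configured exact-method capacity.

    Raised by exact enumeration routines when the state space is too large;
    the message directs callers to the Monte Carlo path instead.
    """
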