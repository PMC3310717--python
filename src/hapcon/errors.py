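"""Exception hierarchy."""


class HapconError(Exception):
    """Base class for all hapcon errors."""


class ParseError(HapconError, ValueError):
    """A file could not be parsed; the message names the offending line/row."""


class EmptyRegionError(HapconError, ValueError):
    """A region query matched no sites."""


class NoEligibleChromosomesError(HapconError, ValueError):
    """Every chromosome was excluded by the missingness cap."""


class UnresolvableConsensusError(HapconError, ValueError):
    """A consensus column had no non-missing allele among the survivors."""


class ConsensusDepletedError(HapconError, ValueError):
    """All survivors were filtered out before the consensus covered the span."""
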