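"""Exception hierarchy. Exit codes: 2 input, 3 sampling, 4 scoring."""


class MinidockError(Exception):
    exit_code = 1


class InputError(MinidockError):
    exit_code = 2


class MolFormatError(InputError):
    pass


class EmptyInputError(InputError):
    pass


class SamplingError(MinidockError):
    exit_code = 3


class ScoringError(MinidockError):
    exit_code = 4
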