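class ValidationError(ValueError):
    """Raised when an input fails a structural precondition.

    The command-line interface maps this to exit code 2; any other
    exception maps to exit code 3.
    """
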