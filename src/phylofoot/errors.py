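"""Exception hierarchy shared across the package."""


class PhylofootError(Exception):
    """Base class for errors raised by phylofoot (user-correctable)."""


class InputError(PhylofootError):
    """Malformed or inconsistent user input (files, tables, parameters)."""


class GuardError(PhylofootError):
    """A combinatorial safety guard was exceeded."""
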