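"""Analytic multiply-accumulate (MAC) accounting.

While a :class:`MacCounter` is active, every primitive in
:mod:`rggcunet.nn.functional` reports the MACs of its forward computation,
derived from its shapes (so the tally is exact and deterministic).  Scopes
let a model attribute counts to named stages.
"""

from __future__ import annotations

from contextlib import contextmanager

_ACTIVE: list["MacCounter"] = []


class MacCounter:
    def __init__(self):
        self.total: int = 0
        self.by_scope: dict[str, int] = {}
        self.unsupported: list[str] = []
        self._stack: list[str] = []

    # -- context management ---------------------------------------------
    def __enter__(self):
        _ACTIVE.append(self)
        return self

    def __exit__(self, *exc):
        _ACTIVE.remove(self)
        return False

    @contextmanager
    def scope(self, name: str):
        self._stack.append(name)
        try:
            yield
        finally:
            self._stack.pop()

    # -- recording --------------------------------------------------------
    def add(self, macs: int) -> None:
        self.total += int(macs)
        key = ".".join(self._stack) if self._stack else "(top)"
        self.by_scope[key] = self.by_scope.get(key, 0) + int(macs)

    def warn_unsupported(self, what: str) -> None:
        self.unsupported.append(what)


def active() -> MacCounter | None:
    return _ACTIVE[-1] if _ACTIVE else None


def add_macs(macs: int) -> None:
    c = active()
    if c is not None:
        c.add(macs)


@contextmanager
def scope(name: str):
    c = active()
    if c is None:
        yield
    else:
        with c.scope(name):
            yield
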