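"""Small shared builders for hand-constructed timelines."""

from __future__ import annotations

from crcscreen import Person


def person_stub(death_age, cause="other", cancers=(), stool=(), colos=()):
    """A Person with a hand-built timeline (no simulation involved)."""
    return Person(id=0, sex="female", frailty=1.0,
                  other_cause_death_age=death_age if cause == "other" else 120.0,
                  death_age=death_age, death_cause=cause,
                  cancers=list(cancers), stool_tests=list(stool),
                  colonoscopies=list(colos))
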