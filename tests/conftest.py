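import pytest

from boolpath.rules import BooleanRule, RuleSet


@pytest.fixture
def chain_rules() -> RuleSet:
    """Two-node chain: A holds its state, B copies A."""
    return RuleSet(
        {
            "A": BooleanRule("A", (("A", 1),), (0, 1), "A", 0),
            "B": BooleanRule("B", (("A", 1),), (0, 1), "A", 0),
        }
    )


@pytest.fixture
def toy_kgml() -> str:
    """Three-entry KGML: entry 1 holds two gene members activating B; C inhibits B."""
    return """<?xml version="1.0"?>
<pathway name="path:toy" org="hsa" number="00001" title="toy pathway">
  <entry id="1" name="hsa:1 hsa:2" type="gene">
    <graphics name="A1, A2" type="rectangle"/>
  </entry>
  <entry id="2" name="hsa:3" type="gene">
    <graphics name="B" type="rectangle"/>
  </entry>
  <entry id="3" name="hsa:4" type="gene">
    <graphics name="C" type="rectangle"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="3" entry2="2" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>
"""
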