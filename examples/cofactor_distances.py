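"""Cofactor recognition and edge-to-edge distances on a synthetic flavin pair.

Builds two isoalloxazine ring systems with a known 5.7 Å closest gap (the
FMN-FMN separation seen when the shuttle domain docks at its acceptor),
extracts them through the cofactor registry and reports the distance chain.
"""

from redoxmap import build_chain_report, extract_cofactors, fixtures

s = fixtures.make_flavin_pair(5.7)
cofactors = extract_cofactors(s)
print("recognized:", [(c.label, c.kind, len(c.edge_atoms)) for c in cofactors])

report = build_chain_report(cofactors, [c.label for c in cofactors])
print(report.to_tsv())
print("-> 5.7 Å is well inside the 14 Å fast-transfer threshold: this pair is")
print("   classified 'fast' and its ruler rate is far above turnover.")
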