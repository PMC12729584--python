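"""Map an integer chromosome to a symbolic expression via the BNF grammar.

Each codon V picks production rule V mod NR at the leftmost nonterminal.
The ten-codon chromosome below derives the expression (x2+cos(x3)) over a
3-dimensional input.
"""

from gefc.grammar import default_feature_grammar, map_chromosome, serialize_expression

codons = (9, 8, 6, 4, 16, 10, 17, 23, 8, 14)
grammar = default_feature_grammar(d=3)
result = map_chromosome(codons, grammar)

print(f"chromosome: {codons}")
for symbol, codon, rule in result.derivation:
    print(f"  <{symbol}>: {codon} mod {grammar.n_rules(symbol)} = {rule}")
print(f"expression: {serialize_expression(result.expression)}")
print(f"codons consumed: {result.codons_consumed}, wraps: {result.wraps_used}")
# Each line is one derivation step: the codon, the rule count of the symbol
# being expanded, and the chosen rule index. The final line is the mapped
# arithmetic expression over the input features x1..x3.
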