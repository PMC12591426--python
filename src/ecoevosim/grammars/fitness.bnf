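# Fitness grammar: compatibility between derived traits T(i,j) and regional
# environmental properties X(i,j).  gauss(a,b) = exp(-8 (a-b)^2) is a sharp
# match kernel that punishes trait-environment mismatch; lin(a,b) = 1-|a-b|
# is a broader linear match; sim(a,b) = 1/(1+(a-b)^2) is the most tolerant;
# low = min models limiting-factor trade-offs.  Every derivable expression
# references at least one trait and one environmental property by
# construction; the engine clamps the result to [0, 1].
<fit> ::= <m> | avg(<m>, <m>) | mul(<m>, <m>) | low(<m>, <m>)
<m> ::= gauss(<t>, <e>) | lin(<t>, <e>) | sim(<t>, <e>) | gauss(<t>, avg(<e>, <e>))
<t> ::= T(<d>,<d>)
<e> ::= X(<d>,<d>)
<d> ::= 0 | 1 | 2 | 3
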