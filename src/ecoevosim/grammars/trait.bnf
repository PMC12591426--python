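# Trait grammar: expressions over normalized environmental inputs X(i,j),
# built from polynomial, exponential, logarithmic and trigonometric
# primitives.  X(a,b) reads environmental property (4*a+b) mod nenv; all
# primitives are protected so every expression evaluates to a float.
<expr> ::= <bin>(<expr>, <expr>) | <un>(<expr>) | <var> | <const>
<bin> ::= add | sub | mul | div
<un> ::= sin | cos | pexp | plog
<var> ::= X(<d>,<d>)
<const> ::= 0.2 | 0.5 | 0.8 | <d>
<d> ::= 0 | 1 | 2 | 3
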