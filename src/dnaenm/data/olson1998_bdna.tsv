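# Dinucleotide base-step parameters averaged over B-DNA X-ray crystal
# structures of protein-DNA complexes (Olson/Gorin/Lu/Hock/Zhurkin set).
# Angles in degrees, translations in Angstrom.  The 10 unique steps are
# listed; the 6 remaining steps follow from the reverse-complement sign
# convention (twist/roll/slide/rise invariant, tilt/shift negated).
step	twist	roll	tilt	shift	slide	rise
AA	35.1	0.7	-1.4	-0.03	-0.08	3.27
AC	31.5	0.7	-0.1	0.13	-0.58	3.36
AG	31.9	4.5	-1.7	0.09	-0.25	3.34
AT	29.3	1.1	0.0	0.00	-0.59	3.31
CA	34.5	4.7	0.5	0.09	0.53	3.33
CC	33.7	3.6	-0.1	0.05	-0.22	3.42
CG	36.1	5.4	0.0	0.00	0.41	3.39
GA	36.9	1.9	-1.5	-0.28	0.09	3.37
GC	40.0	0.3	0.0	0.00	-0.38	3.40
TA	37.8	3.3	0.0	0.00	0.05	3.42
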