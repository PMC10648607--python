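transcript_id	liver	Huh7	HepG2	uniprot_id	status
HNRNPR-203	-	-	+	O43390-2	Protein isoform
HNRNPR-202	-	-	+	O43390-1	Canonical form
DAP3-214	-	-	+	P51398-2	Protein isoform
RPL31-203	-	-	+	P62899-2	Protein isoform
EEF1B2-201	-	+	-	P24534-1	Canonical form
RPL32-206	-	-	+	P62910-1	Canonical form
EIF4G1-203	-	+	-	Q04637-5	Protein isoform
RPL26L1-206	-	-	+	Q9UNX3-1	Canonical form
RPS10-207	-	-	+	A0A2R8Y7H1	Predicted
MRPS33-202	-	+	-	Q9Y291-1	Canonical form
MRPS33-203	-	+	-	C9JBY7	Predicted
MRPL11-203	-	+	-	Q9Y3B7-2	Protein isoform
RPL23A-206	-	+	-	K7EMA7	Predicted
DDX5-223	-	+	-	A0A0G2JLI4	Predicted
ILF3-222	-	+	-	K7EMZ8	Predicted
EIF3K-213	-	+	-	K7EK53	Predicted
EIF6-209	+	-	-	P56537-1	Canonical form
EIF6-202	-	+	-	P56537-2	Protein isoform
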