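##description: toy single-transcript gene models for the five RMS fusion partners (synthetic coordinates; exon k of each gene spans [1000*k, 1000*k+200) in 0-based terms)
chr2	fusionwire	exon	1001	1200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "1";
chr2	fusionwire	exon	2001	2200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "2";
chr2	fusionwire	exon	3001	3200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "3";
chr2	fusionwire	exon	4001	4200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "4";
chr2	fusionwire	exon	5001	5200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "5";
chr2	fusionwire	exon	6001	6200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "6";
chr2	fusionwire	exon	7001	7200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "7";
chr2	fusionwire	exon	8001	8200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "8";
chr2	fusionwire	exon	9001	9200	.	+	.	gene_id "PAX3"; transcript_id "PAX3.t1"; exon_number "9";
chr1	fusionwire	exon	1001	1200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "1";
chr1	fusionwire	exon	2001	2200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "2";
chr1	fusionwire	exon	3001	3200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "3";
chr1	fusionwire	exon	4001	4200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "4";
chr1	fusionwire	exon	5001	5200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "5";
chr1	fusionwire	exon	6001	6200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "6";
chr1	fusionwire	exon	7001	7200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "7";
chr1	fusionwire	exon	8001	8200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "8";
chr1	fusionwire	exon	9001	9200	.	+	.	gene_id "PAX7"; transcript_id "PAX7.t1"; exon_number "9";
chr13	fusionwire	exon	1001	1200	.	+	.	gene_id "FOXO1"; transcript_id "FOXO1.t1"; exon_number "1";
chr13	fusionwire	exon	2001	2200	.	+	.	gene_id "FOXO1"; transcript_id "FOXO1.t1"; exon_number "2";
chr13	fusionwire	exon	3001	3200	.	+	.	gene_id "FOXO1"; transcript_id "FOXO1.t1"; exon_number "3";
chr2	fusionwire	exon	101001	101200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "1";
chr2	fusionwire	exon	102001	102200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "2";
chr2	fusionwire	exon	103001	103200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "3";
chr2	fusionwire	exon	104001	104200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "4";
chr2	fusionwire	exon	105001	105200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "5";
chr2	fusionwire	exon	106001	106200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "6";
chr2	fusionwire	exon	107001	107200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "7";
chr2	fusionwire	exon	108001	108200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "8";
chr2	fusionwire	exon	109001	109200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "9";
chr2	fusionwire	exon	110001	110200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "10";
chr2	fusionwire	exon	111001	111200	.	+	.	gene_id "INO80D"; transcript_id "INO80D.t1"; exon_number "11";
chr2	fusionwire	exon	201001	201200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "1";
chr2	fusionwire	exon	202001	202200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "2";
chr2	fusionwire	exon	203001	203200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "3";
chr2	fusionwire	exon	204001	204200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "4";
chr2	fusionwire	exon	205001	205200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "5";
chr2	fusionwire	exon	206001	206200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "6";
chr2	fusionwire	exon	207001	207200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "7";
chr2	fusionwire	exon	208001	208200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "8";
chr2	fusionwire	exon	209001	209200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "9";
chr2	fusionwire	exon	210001	210200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "10";
chr2	fusionwire	exon	211001	211200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "11";
chr2	fusionwire	exon	212001	212200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "12";
chr2	fusionwire	exon	213001	213200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "13";
chr2	fusionwire	exon	214001	214200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "14";
chr2	fusionwire	exon	215001	215200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "15";
chr2	fusionwire	exon	216001	216200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "16";
chr2	fusionwire	exon	217001	217200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "17";
chr2	fusionwire	exon	218001	218200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "18";
chr2	fusionwire	exon	219001	219200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "19";
chr2	fusionwire	exon	220001	220200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "20";
chr2	fusionwire	exon	221001	221200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "21";
chr2	fusionwire	exon	222001	222200	.	+	.	gene_id "NCOA1"; transcript_id "NCOA1.t1"; exon_number "22";
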