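accession	ortholog	protein_name	peptide	site_labels	cond_low	cond_opt	cond_high	precursor_ppm	product_ppm	missed_cleavages
SPLC1_S204380	NIES39_A07260	16S rRNA (uracil(1498)-N(3))-methyltransferase	TGQGKGyVYNSLLLAIGPEGGWtTPEVEEAINRR	Y192y T208t	1	0	0	10.0	25.0	2
SPLC1_S204380	NIES39_A07260	16S rRNA (uracil(1498)-N(3))-methyltransferase	TGQGKGyVYNSLLLAIGPEGGWTtPEVEEAINRR	Y192y T209t	1	0	0	10.0	25.0	2
SPLC1_S204380	NIES39_A07260	16S rRNA (uracil(1498)-N(3))-methyltransferase	tGQGKGyVYNSLLLAIGPEGGWTTPEVEEAINRR	T186t Y192y	1	0	0	10.0	25.0	2
SPLC1_S204380	NIES39_A07260	16S rRNA (uracil(1498)-N(3))-methyltransferase	TGQGKGYVYNSLLLAIGPEGGWttPEVEEAINRR	T208t T209t	1	1	1	10.0	25.0	2
SPLC1_S204380	NIES39_A07260	16S rRNA (uracil(1498)-N(3))-methyltransferase	GYVYNSLLLAIGPEGGWTTPEVEEAINRRFQPVSLGsR	S227s	1	0	0	10.0	25.0	2
SPLC1_S101160	NIES39_Q01000	adenylate cyclase	SITNTVLEtGNAILTSDAHVDER	T215t	1	1	0	10.0	25.0	0
SPLC1_S101160	NIES39_Q01000	adenylate cyclase	SITNTVLETGNAILTsDAHVDER	S222s	1	0	0	10.0	25.0	0
SPLC1_S208580	NIES39_K04210	adenylate/guanylate cyclase domain-containing protein	LWQSQNLPVIEMRVGIFtGPIVAGSLGsR	T556t S566s	1	0	0	10.0	25.0	1
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	VLEYAVKAARALNCEIAPYsK	S82s	1	0	0	10.0	25.0	2
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	IGItRLHMEEDAGKLVHGGsDR	T132t S148s	1	0	0	10.0	25.0	2
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	LVHGGsDRLAGSTYsMVDFNR	S148s S157s	1	0	0	10.0	25.0	1
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	LVHGGSDRLAGstYSMVDFNR	S154s T155t	1	0	0	10.0	25.0	1
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	LHMEEDAGKLVHGGSDRLAGStySMVDFNR	T155t Y156y	1	0	0	10.0	25.0	2
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	RIVRYLGVsDGNMQEGSLR	S200s	1	1	1	10.0	25.0	2
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	YLGVsDGNMQEGSLR	S200s	1	0	0	10.0	25.0	0
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	CDVNISVRPVGQKEFGtK	T227t	1	0	0	10.0	25.0	1
SPLC1_S082160	NIES39_E03060	aspartyl/glutamyl-tRNA amidotransferase subunit B	VLTDDRtVAQYFEATVAAGADtK	T342t T357t	1	0	0	10.0	25.0	1
SPLC1_S102760	NIES39_Q02320	beta-ketoacyl-[acyl-carrier-protein] synthase II	ALStRNDDPLHACRPFDVGR	T214t	1	0	0	10.0	25.0	1
SPLC1_S208940	NIES39_K04600	cell division protein FtsH	LAEEIVFGEEEVTTGAsNDLQQVTRVAR	S486s	1	0	0	10.0	25.0	1
SPLC1_S208940	NIES39_K04600	cell division protein FtsH	LAEEIVFGEEEVTTGASNDLQQVtRVAR	T493t	1	0	0	10.0	25.0	1
SPLC1_S034010	NIES39_D02960	crossover junction endodeoxyribonuclease RuvA	LFGNHRTNsDIDNLAGACLDALTLQGAGVLMDDR	S231s	1	0	0	10.0	25.0	1
SPLC1_S034010	NIES39_D02960	crossover junction endodeoxyribonuclease RuvA	LFGNHRTNSDIDNLAGACLDALtLQGAGVLMDDR	T245t	1	0	0	10.0	25.0	1
SPLC1_S205200	NIES39_A07940	cytochrome c biogenesis protein	MSETLQTQLYEIAQFANtLVR	T18t	1	1	0	10.0	25.0	0
SPLC1_S540320	NIES39_M01840	diguanylate cyclase	LRHSAsHDSLTDLWNR	S755s	1	0	0	10.0	25.0	1
SPLC1_S540320	NIES39_M01840	diguanylate cyclase	LtDSVDsHILARLGGDEFTILLENIRDIQEAIDVAER	T821t S826s	1	0	0	10.0	25.0	2
SPLC1_S540320	NIES39_M01840	diguanylate cyclase	LTDsVDsHILARLGGDEFTILLENIRDIQEAIDVAER	S823s S826s	1	0	0	10.0	25.0	2
SPLC1_S270810	NIES39_J05180	DNA-binding protein	AILDLAFSAISQEIEsGQPVVVRGLGK	S38s	1	0	0	10.0	25.0	1
SPLC1_S430280	NIES39_O01770	D-tyrosyl-tRNA(Tyr) deacylase	sVQDIGGELLVVSQFTLYGDCR	S68s	1	1	0	10.0	25.0	0
SPLC1_S430280	NIES39_O01770	D-tyrosyl-tRNA(Tyr) deacylase	SVQDIGGELLVVsQFTLYGDCR	S80s	1	0	0	10.0	25.0	0
SPLC1_S430280	NIES39_O01770	D-tyrosyl-tRNA(Tyr) deacylase	SVQDIGGELLVVSQFTLyGDCR	Y85y	1	1	0	10.0	25.0	0
SPLC1_S270380	NIES39_J05540	glutamate synthase	tIVYKGMVRSAVLGEFYR	T234t	1	1	0	10.0	25.0	2
SPLC1_S270380	NIES39_J05540	glutamate synthase	TIVyKGMVRSAVLGEFYR	Y237y	1	1	1	10.0	25.0	2
SPLC1_S082010	NIES39_E02970	histidine kinase	LVHAPSSSSIFHItKLMSR	T206t	1	0	0	10.0	25.0	1
SPLC1_S082010	NIES39_E02970	histidine kinase	LVHAPSSSSIFHITKLMsR	S210s	0	1	1	10.0	25.0	1
SPLC1_S230960	NIES39_L00910	histidine kinase	IGLVSAPPEVFLKtPsEMDEATQK	T320t S322s	1	1	1	10.0	25.0	1
SPLC1_S230960	NIES39_L00910	histidine kinase	IGLVSAPPEVFLKTPsEMDEAtQK	S322s T328t	1	0	0	10.0	25.0	1
SPLC1_S230960	NIES39_L00910	histidine kinase	IVtYLQSsQQELISVNR	T215t S220s	1	0	0	10.0	25.0	0
SPLC1_S230960	NIES39_L00910	histidine kinase	IVTYLQssQQELISVNR	S219s S220s	1	1	0	10.0	25.0	0
SPLC1_S040030	NIES39_D03400	hydrogenase accessory protein HypB	LNsAVIVGDLETDNDAQRLR	S129s	1	0	0	10.0	25.0	1
SPLC1_S260960	ARTHRO_390015	hydroxymethylbilane synthase	EDPADALVVHENHRDKQLDtLPPGAVVGTSSLR	T127t	1	0	0	10.0	25.0	2
SPLC1_S051730	NIES39_D06980	hypothetical protein	FNGDGTLVWAQSIGGSDLDSGNGIAVDDAGNVYATGsFSSR	S285s	1	0	0	10.0	25.0	0
SPLC1_S051730	NIES39_D06980	hypothetical protein	FNGDGTLVWAQSIGGSDLDSGNGIAVDDAGNVYATGSFSsR	S288s	1	0	0	10.0	25.0	0
SPLC1_S130380	NIES39_R00890	hypothetical protein	KYSIADMDsTSGDLAVETYEIVAEMITKEVALGGQVASMR	S149s	1	1	0	10.0	25.0	2
SPLC1_S130380	NIES39_R00890	hypothetical protein	KYSIADMDStSGDLAVETYEIVAEMITKEVALGGQVASMR	T150t	1	0	0	10.0	25.0	2
SPLC1_S130380	NIES39_R00890	hypothetical protein	KYSIADMDSTSGDLAVETYEIVAEMItKEVALGGQVASMR	T167t	1	1	1	10.0	25.0	2
SPLC1_S171520	NIES39_A02180	hypothetical protein	FIPAFGSAIAASWAFAYTGALGEATCVyFGDLMGGK	Y398y	1	1	1	10.0	25.0	0
SPLC1_S171520	NIES39_A02180	hypothetical protein	FIPAFGsAIAASWAFAYTGALGEATCVYFGDLMGGK	S377s	1	0	0	10.0	25.0	0
SPLC1_S202870	NIES39_A05660	hypothetical protein	IWTFEQVQGILyVVVPIRMtVIR	Y56y T64t	1	0	0	10.0	25.0	1
SPLC1_S202870	NIES39_A05660	hypothetical protein	LDMGGLLVyAPVAPTPECIRLVNELVAEYGEVR	Y76y	1	1	0	10.0	25.0	1
SPLC1_S202870	NIES39_A05660	hypothetical protein	LDMGGLLVYAPVAPtPECIRLVNELVAEYGEVR	T82t	1	0	0	10.0	25.0	1
SPLC1_S202870	NIES39_A05660	hypothetical protein	LDMGGLLVYAPVAPTPECIRLVNELVAEyGEVR	Y96y	1	0	0	10.0	25.0	1
SPLC1_S120070	SPLC1_S530570	hypothetical protein	QLVDLTDAKIVyPITFEERK	Y36y	1	1	1	10.0	25.0	2
SPLC1_S120070	SPLC1_S530570	hypothetical protein	QLVDLtDAKIVYPITFEERK	T30t	1	0	0	10.0	25.0	2
SPLC1_S510820	NIES39_O06510	IMP dehydrogenase	LGVTVDIIADLHPINPFNFVMESYAERyPFIYEEQLGR	Y102y	1	0	0	10.0	25.0	1
SPLC1_S510820	NIES39_O06510	IMP dehydrogenase	LGVTVDIIADLHPINPFNFVMESYAERYPFIyEEQLGR	Y106y	1	0	0	10.0	25.0	1
SPLC1_S205080	NIES39_A07830	isoaspartyl peptidase	GGVEtVRKSLYQVITEVYGLLEK	T27t	1	0	0	10.0	25.0	2
SPLC1_S060060	NIES39_D06730	lysophospholipase	MLRLEHISKIYPtGtILK	T13t T15t	1	1	0	10.0	25.0	2
SPLC1_S060060	NIES39_D06730	lysophospholipase	IIAGEVEPTSGEVIKPSSLHIAYLTQEFEVDPARtVREEFWR	T80t	1	1	0	10.0	25.0	2
SPLC1_S060060	NIES39_D06730	lysophospholipase	IIAGEVEPTSGEVIKPSSLHIAYLtQEFEVDPARTVREEFWR	T70t	1	0	0	10.0	25.0	2
SPLC1_S207550	NIES39_K03280	membrane protein	IVSLSSIAGAITIAALMIItGQPLPYQIFAIAAGtYVIWRHR	T180t T195t	1	1	0	10.0	25.0	1
SPLC1_S207550	NIES39_K03280	membrane protein	IVSLSSIAGAITIAALMIItGQPLPyQIFAIAAGTYVIWRHR	T180t Y186y	1	1	0	10.0	25.0	1
SPLC1_S410530		MULTISPECIES: HNH endonuclease	QVIAAQLPDGsALVEFVR	S61s	0	0	0	10.0	25.0	0
SPLC1_S542340		peptidase	VVLVtGIAGFIGSAVARLLISKNQK	T13t	1	0	0	10.0	25.0	2
SPLC1_S542340		peptidase	LASENYMKIysHQYNISSVALR	Y163y S164s	1	0	0	10.0	25.0	1
SPLC1_S542340		peptidase	LASENYMKIYsHQyNISSVALR	S164s Y167y	1	1	0	10.0	25.0	1
SPLC1_S201490	NIES39_A04370	phosphate permease	LsGRTFFHRWQLAEALAEESESWQFQPPITR	S445s	1	0	0	10.0	25.0	2
SPLC1_S201490	NIES39_A04370	phosphate permease	LSGRTFFHRWQLAEALAEESESWQFQPPItR	T473t	1	0	0	10.0	25.0	2
SPLC1_S240360	NIES39_K02580	phosphoglycerate dehydrogenase	SAVNIPGLYPDALEQLKPYLQLAETLGNLVsQLVGGR	S353s	1	0	0	10.0	25.0	0
SPLC1_S082540	NIES39_C04520	CpcD phycobilisome linker domain protein	VTACVPSQTRIRtQR	T18t	1	0	0	10.0	25.0	2
SPLC1_S203810	NIES39_A06620	type I restriction endonuclease subunit R	LQAVRyKQsFDK	Y606y S609s	1	1	1	10.0	25.0	2
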