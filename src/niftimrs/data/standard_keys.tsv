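# Standard-defined header-extension keys, one per line.
# Columns (tab-separated): name	value_type	units	private	doc
# value_type is one of: number, string, number-array, string-array, object, bool
# units "-" means dimensionless / not applicable.
EchoTime	number	s	false	Echo time of the acquisition
RepetitionTime	number	s	false	Repetition time of the acquisition
InversionTime	number	s	false	Inversion time for inversion-prepared sequences
MixingTime	number	s	false	Mixing time for stimulated-echo sequences
ExcitationFlipAngle	number	degrees	false	Nominal excitation flip angle
TxOffset	number	ppm	false	Transmitter offset relative to the receiver reference
AcquisitionStartTime	string	-	true	Clock time at which the acquisition started
SequenceName	string	-	false	Scanner-reported pulse sequence identifier
ProtocolName	string	-	false	Operator-chosen protocol name
WaterSuppressed	bool	-	false	Whether water suppression was applied
WaterSuppressionType	string	-	false	Water suppression scheme (e.g. CHESS, VAPOR)
SequenceTriggered	bool	-	false	Whether the sequence was physiologically triggered
Manufacturer	string	-	false	Scanner manufacturer
ManufacturersModelName	string	-	false	Scanner model name
DeviceSerialNumber	string	-	true	Scanner serial number
SoftwareVersions	string	-	false	Scanner software version string
InstitutionName	string	-	false	Institution where the data was acquired
InstitutionAddress	string	-	false	Address of the acquiring institution
TxCoil	string	-	false	Transmit coil name
RxCoil	string	-	false	Receive coil name
PatientPosition	string	-	false	Subject position in the scanner (e.g. HFS)
PatientName	string	-	true	Subject name
PatientID	string	-	true	Subject identifier
PatientWeight	number	kg	false	Subject weight
PatientDoB	string	-	true	Subject date of birth
PatientSex	string	-	false	Subject sex (M/F/O)
ConversionMethod	string	-	false	Program used to convert the data to this format
ConversionTime	string	-	false	Date and time of conversion
OriginalFile	string-array	-	true	Names of the source data files
ProcessingApplied	object	-	false	Sequential record of processing steps
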