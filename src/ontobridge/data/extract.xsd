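<?xml version="1.0" encoding="UTF-8"?>
<!-- Strict schema for the ehrExtract wire dialect, version 1.
     Kind-specific attribute rules (e.g. conceptId only on coded values)
     are enforced by the parser on top of this schema. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="urn:ontobridge:extract:1"
           xmlns:ob="urn:ontobridge:extract:1"
           elementFormDefault="qualified">

  <xs:element name="ehrExtract">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="entry" type="ob:EntryType" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="extractId" type="xs:string" use="required"/>
      <xs:attribute name="subjectId" type="xs:string" use="required"/>
      <xs:attribute name="timeCreated" type="xs:dateTime" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="EntryType">
    <xs:sequence>
      <xs:element name="element" type="ob:ElementType" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="archetypeId" type="xs:string" use="required"/>
    <xs:attribute name="rcId" type="xs:nonNegativeInteger"/>
  </xs:complexType>

  <xs:complexType name="ElementType">
    <xs:sequence>
      <xs:element name="value" type="ob:ValueType"/>
    </xs:sequence>
    <xs:attribute name="nodeId" use="required">
      <xs:simpleType>
        <xs:restriction base="xs:string">
          <xs:pattern value="at[0-9]{4}"/>
        </xs:restriction>
      </xs:simpleType>
    </xs:attribute>
    <xs:attribute name="name" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="ValueType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="kind" use="required">
          <xs:simpleType>
            <xs:restriction base="xs:string">
              <xs:enumeration value="coded"/>
              <xs:enumeration value="date"/>
              <xs:enumeration value="quantity"/>
              <xs:enumeration value="text"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:attribute>
        <xs:attribute name="conceptId" type="xs:string"/>
        <xs:attribute name="schemeUri" type="xs:anyURI"/>
        <xs:attribute name="unit" type="xs:string"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

</xs:schema>
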